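"""Kinetics, currents and right-hand sides of the two-compartment model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrcell import (ModelParameters, approximation_error, chi, gating_rate,
                     ionic_currents, rhs_fast, rhs_full, smooth_gate)
from pyrcell import model
from pyrcell.symbolic import jac_smooth, rhs_smooth


def random_state(rng):
    return np.array([
        rng.uniform(-90, 40), rng.uniform(-90, 40),
        rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 1),
        rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 400),
    ])


class TestGatingRates:
    @pytest.mark.parametrize("gate,U,a_exp,b_exp", [
        # removable singularity of alpha_m at Vs = -46.9: limit 0.32*4
        ("m", -46.9, 1.28, None),
        # beta_q is the constant 0.001; alpha_q saturates at 0.01
        ("q_orig", 1000.0, 0.01, 0.001),
        ("q_orig", 100.0, 0.002, 0.001),
    ])
    def test_printed_rate_values(self, gate, U, a_exp, b_exp):
        a, b = gating_rate(gate, U)
        assert a == pytest.approx(a_exp, rel=1e-10)
        if b_exp is not None:
            assert b == pytest.approx(b_exp, rel=1e-12)

    @pytest.mark.parametrize("gate,U0,scale", [
        ("m", -46.9, 4.0), ("n", -24.9, 5.0), ("s", -8.9, 5.0),
    ])
    def test_removable_singularities_are_continuous(self, gate, U0, scale):
        fa = gating_rate(gate, U0)
        lo = gating_rate(gate, U0 - 1e-6)
        hi = gating_rate(gate, U0 + 1e-6)
        which = 0 if gate != "s" else 1  # the singular rate of each gate
        assert fa[which] == pytest.approx(lo[which], rel=1e-5)
        assert fa[which] == pytest.approx(hi[which], rel=1e-5)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError):
            gating_rate("z", 0.0)
        with pytest.raises(ValueError):
            gating_rate("m", float("nan"))

    def test_xinf_bounded_tau_positive(self):
        for V in np.linspace(-100, 60, 161):
            for g in ("m", "n", "h", "s", "c"):
                xi = model.x_inf(g, V)
                assert 0.0 <= xi <= 1.0 + 1e-12
                assert model.tau_x(g, V) > 0
        for Ca in np.linspace(0, 500, 101):
            assert model.tau_x("q", Ca) > 0
            assert model.x_inf("q", Ca) >= 0


class TestSmoothGates:
    def test_fitted_values_at_origin(self):
        # direct evaluation of the printed double-exponential coefficients
        qi, tq = smooth_gate("q", 0.0)
        assert qi == pytest.approx(0.7894 - 0.7292, abs=1e-12)
        assert tq == pytest.approx(657.9 + 301.8, abs=1e-9)
        ci, tc = smooth_gate("c", 0.0)
        assert tc == pytest.approx(3.627, rel=1e-12)
        assert 0.99 < ci <= 1.0

    def test_cinf_stable_at_very_negative_voltage(self):
        ci, _ = smooth_gate("c", -500.0)
        assert 0.0 <= ci < 1e-10 or math.isfinite(ci)

    def test_unknown_gate(self):
        with pytest.raises(ValueError):
            smooth_gate("h", 0.0)


class TestChi:
    def test_original_piecewise(self):
        assert chi(250.0, "original") == 1.0
        assert chi(125.0, "original") == 0.5
        assert chi(400.0, "original") == 1.0

    def test_smooth_close_to_original(self):
        assert abs(chi(125.0, "smooth") - 0.5) < 0.08
        grid = np.linspace(0, 500, 400)
        err = [abs(chi(c, "smooth") - chi(c, "original")) for c in grid]
        assert max(err) < 0.08


class TestCurrents:
    def test_zero_driving_force(self):
        pr = ModelParameters()
        y = np.array([pr.VNa, -60.0, 0.5, 0.5, 0.1, 0.1, 0.1, 10.0])
        assert ionic_currents(y, pr).INa == 0.0
        y2 = np.array([-60.0, -60.0, 0.5, 0.5, 0.1, 0.1, 0.1, 10.0])
        cb = ionic_currents(y2, pr)
        assert cb.ISD == 0.0 and cb.IDS == 0.0
        y3 = np.array([-50.0, pr.VK, 0.5, 0.5, 0.1, 0.1, 1.0, 10.0])
        assert ionic_currents(y3, pr).IKAHP == 0.0

    @settings(max_examples=60, deadline=None)
    @given(st.floats(-90, 40), st.floats(-90, 40))
    def test_coupling_currents_cancel(self, vs, vd):
        pr = ModelParameters()
        y = np.array([vs, vd, 0.5, 0.5, 0.1, 0.1, 0.1, 10.0])
        cb = ionic_currents(y, pr)
        assert cb.ISD == -cb.IDS


class TestRHS:
    def test_reference_and_generated_paths_agree(self):
        rng = np.random.default_rng(0)
        pr = ModelParameters(ISapp=0.5)
        for _ in range(20):
            y = random_state(rng)
            np.testing.assert_allclose(
                rhs_full(y, pr), rhs_smooth(y, pr.theta()),
                rtol=1e-12, atol=1e-12)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        pr = ModelParameters(ISapp=0.75)
        th = pr.theta()
        for _ in range(5):
            y = random_state(rng)
            J = jac_smooth(y, th)
            Jfd = np.empty((8, 8))
            for j in range(8):
                h = 1e-6 * max(1.0, abs(y[j]))
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                Jfd[:, j] = (rhs_smooth(yp, th) - rhs_smooth(ym, th)) / (2 * h)
            np.testing.assert_allclose(J, Jfd, rtol=2e-5, atol=1e-7)

    def test_ca_nullcline(self):
        # dCa/dt = 0 exactly when Ca = -(0.13/0.075) * ICa
        pr = ModelParameters()
        y = np.array([-60.0, -40.0, 0.9, 0.1, 0.3, 0.2, 0.1, 0.0])
        ica = ionic_currents(y, pr).ICa
        y[7] = -(0.13 / 0.075) * ica
        assert rhs_full(y, pr)[7] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonfinite_state(self):
        pr = ModelParameters()
        y = np.full(8, np.nan)
        with pytest.raises(ValueError):
            rhs_full(y, pr)

    def test_fast_subsystem_is_restriction(self):
        pr = ModelParameters(ISapp=0.3)
        rng = np.random.default_rng(2)
        y = random_state(rng)
        full = rhs_full(y, pr)
        fast_q = rhs_fast(np.delete(y, 6), {"q": y[6]}, pr)
        np.testing.assert_allclose(fast_q, np.delete(full, 6), rtol=1e-12)
        fast_both = rhs_fast(y[:6], {"q": y[6], "Ca": y[7]}, pr)
        np.testing.assert_allclose(fast_both, full[:6], rtol=1e-12)
        with pytest.raises(ValueError):
            rhs_fast(y, {}, pr)


class TestApproximationError:
    def test_all_fitted_functions_within_order_1e2(self):
        errs = approximation_error()
        for name, dat in errs.items():
            assert float(np.max(dat["error"])) <= 0.08, name

    def test_chi_error_where_original_saturates(self):
        errs = approximation_error()
        dat = errs["chi"]
        sat = dat["grid"] >= 260.0
        np.testing.assert_allclose(dat["error"][sat],
                                   np.abs(dat["smooth"][sat] - 1.0))
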