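"""Limit-cycle machinery validated against the Stuart-Landau closed form.

For r' = r(p - r^2), theta' = omega the cycle has radius sqrt(p), period
2*pi/omega and nontrivial Floquet multiplier exp(-2 p T) exactly, making it
an independent oracle for the shooting solver, the monodromy assembly and
the Hopf-started cycle.
"""

import numpy as np
import pytest

from pyrcell import (CallableSystem, continue_cycles, cycle_from_attractor,
                     cycle_from_hopf)
from pyrcell.equilibria import BifurcationPoint
from pyrcell.orbits import _fit_asymptote

OMEGA = 2.0


def sl_system():
    def f(y, p):
        x, z = y
        r2 = x * x + z * z
        return np.array([p * x - OMEGA * z - x * r2,
                         OMEGA * x + p * z - z * r2])
    return CallableSystem(f, 2)


@pytest.fixture(scope="module")
def sl_cycle():
    return cycle_from_attractor(sl_system(), 0.5, init=np.array([0.3, 0.0]),
                                t_settle=60.0, m=20, max_period=40.0)


def test_period_radius_and_multiplier_exact(sl_cycle):
    c = sl_cycle
    assert c.period == pytest.approx(2 * np.pi / OMEGA, rel=1e-8)
    assert np.hypot(*c.nodes[0]) == pytest.approx(np.sqrt(0.5), rel=1e-8)
    assert abs(c.trivial_multiplier - 1.0) < 1e-3
    mu = c.nontrivial_multipliers()[0]
    assert mu.real == pytest.approx(np.exp(-2 * 0.5 * c.period), rel=1e-6)
    assert c.stable


def test_cycle_from_hopf_small_amplitude():
    hb = BifurcationPoint("HB", 0.0, np.zeros(2), {"omega": OMEGA})
    c = cycle_from_hopf(sl_system(), hb, eps=0.05, m=16)
    # amplitude eps fixes the parameter at p = eps^2 for this normal form
    assert c.p == pytest.approx(0.05 ** 2, rel=1e-3)
    assert c.period == pytest.approx(2 * np.pi / OMEGA, rel=0.05)


def test_continuation_tracks_exact_multiplier(sl_cycle):
    br = continue_cycles(sl_system(), sl_cycle, (0.05, 2.0), direction=+1,
                         h0=0.1, max_steps=40)
    assert br.p_values[-1] > 1.5
    np.testing.assert_allclose(br.periods, 2 * np.pi / OMEGA, rtol=1e-6)
    for c in br.cycles:
        if c.multipliers is None:
            continue
        assert abs(c.trivial_multiplier - 1.0) < 1e-3
        mu = c.nontrivial_multipliers()[0].real
        assert mu == pytest.approx(np.exp(-2 * c.p * c.period), rel=1e-5)


@pytest.mark.parametrize("law,pstar", [("log", 0.3), ("sqrt", -0.2)])
def test_asymptote_fit_recovers_known_divergence(law, pstar):
    ps = pstar + np.geomspace(1e-4, 0.3, 12)
    Ts = (50.0 - 12.0 * np.log(ps - pstar) if law == "log"
          else 10.0 + 4.0 / np.sqrt(ps - pstar))
    est, sse = _fit_asymptote(ps, Ts, law)
    assert est == pytest.approx(pstar, abs=2e-4)
    assert sse < 1e-9
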