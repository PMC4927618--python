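"""Equilibrium solving and continuation, checked against closed forms.

The fold and Hopf detectors are validated on planar normal forms whose
bifurcation locations are known exactly, then on the cell model where the
solver is cross-checked against long time integration.
"""

import numpy as np
import pytest

from pyrcell import (CallableSystem, CellSystem, ModelParameters,
                     continue_branch, integrate, solve_equilibrium)
from pyrcell.simulate import default_initial_state


def test_fold_normal_form_location():
    # y' = p - y^2 : equilibria y = +-sqrt(p), fold exactly at p = 0
    sys_ = CallableSystem(lambda y, p: np.array([p - y[0] ** 2]), 1)
    br = continue_branch(sys_, np.array([1.0]), 1.0, (-1.0, 2.0),
                         direction=-1, ds0=0.05, ds_max=0.2)
    folds = br.bif("SN")
    assert len(folds) == 1
    assert folds[0].p == pytest.approx(0.0, abs=1e-6)
    assert abs(folds[0].diagnostic["zero_eig"].real) < 1e-6
    # the branch traverses the fold onto the unstable sheet
    assert br.points[-1].y[0] < 0


def test_hopf_normal_form_location_and_frequency():
    om = 3.0

    def f(y, p):
        x, z = y
        r2 = x * x + z * z
        return np.array([p * x - om * z - x * r2,
                         om * x + p * z - z * r2])

    sys_ = CallableSystem(f, 2)
    br = continue_branch(sys_, np.zeros(2), -1.0, (-1.0, 1.0), direction=+1,
                         ds0=0.05, ds_max=0.1)
    hbs = br.bif("HB")
    assert len(hbs) == 1
    assert hbs[0].p == pytest.approx(0.0, abs=1e-6)
    assert hbs[0].diagnostic["omega"] == pytest.approx(om, rel=1e-6)


def test_solver_agrees_with_long_integration():
    pars = ModelParameters(ISapp=-1.0)
    traj = integrate(pars, t_span=8000.0)
    sys_ = CellSystem(pars, "ISapp")
    y, eig = solve_equilibrium(sys_, default_initial_state(pars), -1.0)
    np.testing.assert_allclose(traj.y[-1], y, rtol=1e-4, atol=1e-5)
    assert np.all(eig.real < 0)  # hyperpolarised rest is a stable node
    assert y[0] < -65.0


def test_depolarised_state_near_minus_30mV():
    pars = ModelParameters(ISapp=25.0)
    sys_ = CellSystem(pars, "ISapp")
    traj = integrate(pars, t_span=4000.0)
    y, eig = solve_equilibrium(sys_, traj.y[-1], 25.0)
    assert -32.0 < y[0] < -27.0
    assert np.all(eig.real < 0)


def test_branch_points_satisfy_equilibrium_and_stability_labels():
    pars = ModelParameters()
    sys_ = CellSystem(pars, "ISapp")
    y0, _ = solve_equilibrium(sys_, default_initial_state(pars), -1.0)
    br = continue_branch(sys_, y0, -1.0, (-30.0, 30.0), direction=+1,
                         ds_max=0.25)
    for pt in br.points[::5]:
        res = np.linalg.norm(sys_.f(pt.y, pt.p) * sys_.weights)
        assert res < 1e-7
        n_unst = int(np.sum(pt.eigvals.real > 1e-9))
        assert n_unst == pt.n_unstable
        assert (pt.stability == "stable_node") == (n_unst == 0)


def test_branch_refines_under_smaller_steps():
    pars = ModelParameters()
    sys_ = CellSystem(pars, "ISapp")
    y0, _ = solve_equilibrium(sys_, default_initial_state(pars), -1.0)
    coarse = continue_branch(sys_, y0, -1.0, (-5.0, 1.0), direction=+1,
                             ds_max=0.25, detect=False)
    fine = continue_branch(sys_, y0, -1.0, (-5.0, 1.0), direction=+1,
                           ds_max=0.05, detect=False)
    # every coarse point lies on the fine branch (small Hausdorff distance)
    w = np.append(sys_.weights, sys_.pweight)
    zf = np.array([np.append(pt.y, pt.p) * w for pt in fine.points])
    for pt in coarse.points:
        zc = np.append(pt.y, pt.p) * w
        assert np.min(np.linalg.norm(zf - zc, axis=1)) < 0.05
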