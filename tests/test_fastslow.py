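"""Fast-slow dissection: timescales, frozen-variable dynamics, diagrams."""

import numpy as np
import pytest

from pyrcell import (CellSystem, ModelParameters, build_fast_diagram,
                     integrate_system, rhs_fast, solve_equilibrium,
                     timescale_separation)
from pyrcell.simulate import Trajectory, classify_firing, default_initial_state


@pytest.fixture(scope="module")
def vlf_params():
    return ModelParameters(ISapp=0.3)


def test_timescale_premise(vlf_params):
    ts = timescale_separation(vlf_params)
    # fast gates settle within a few ms over the effective voltage ranges
    for key in ("tau_h_max", "tau_n_max", "tau_s_max", "tau_c_max"):
        assert ts[key] < 6.0
    assert ts["tau_Ca"] == pytest.approx(1.0 / 0.075)
    assert 100.0 < ts["tau_q_min"] < ts["tau_q_max"] <= 1000.0


def test_full_equilibrium_restricts_to_fast_fixed_point():
    pars = ModelParameters(ISapp=-1.0)
    sys_full = CellSystem(pars, "ISapp")
    y, _ = solve_equilibrium(sys_full, default_initial_state(pars), -1.0)
    # freezing (q, Ca) at the equilibrium's own values leaves the fast
    # components exactly at a fixed point
    d = rhs_fast(y[:6], {"q": y[6], "Ca": y[7]}, pars)
    assert np.linalg.norm(d) < 1e-8


def test_bursting_persists_with_q_frozen(vlf_params):
    sysq = CellSystem(vlf_params, "q")
    y0 = default_initial_state(vlf_params)
    free = [0, 1, 2, 3, 4, 5, 7]  # q removed
    traj = integrate_system(sysq, 0.05, y0[free], t_span=9000.0,
                            rtol=1e-8, atol=1e-8)
    # re-embed for the spike/burst tooling (insert frozen q back)
    y_full = np.insert(traj.y, 6, 0.05, axis=1)
    full = Trajectory(traj.t, y_full, vlf_params)
    fp = classify_firing(full, transient=2000.0)
    assert fp.event_type == "burst"
    assert len(fp.events) >= 2


def test_q_diagram_snic_and_ca_diagram_folds(vlf_params):
    dq = build_fast_diagram(vlf_params, "q")
    assert "SNIC" in dq.labels
    assert 0.0 < dq.labels["SNIC"].p < 0.2
    dca = build_fast_diagram(vlf_params, "Ca")
    # five folds and the depolarised-branch Hopf, as published
    assert {"SN1", "SN2", "SN3", "SN4", "SN5", "HB"} <= set(dca.labels)
    assert dca.labels["SN1"].p < dca.labels["SN5"].p
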