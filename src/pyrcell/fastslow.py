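"""Fast-slow dissection of bursting.

Calcium decays with a fixed 1/0.075 ~ 13.3 ms time constant and the AHP
activation q relaxes over hundreds of ms, while every other gate settles in
a few ms, so the model splits into a fast 6-D membrane subsystem driven by
the two slow variables.  Freezing one slow variable (q, or Ca) at a
parameter value and computing the bifurcation diagram of the remaining
subsystem explains the burst: the diagram in Ca shows a fold of the
hyperpolarised branch (burst initiation) and a subcritical Hopf of the
depolarised branch (burst termination), making very-low-frequency bursting
a fold/subHopf burster; the diagram in q shows that the intraburst dynamics
survive with q fixed — q only gates part of the interburst interval through
a SNIC of the hyperpolarised branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .dynsys import CellSystem
from .equilibria import (BifurcationPoint, ContinuationError,
                         EquilibriumBranch, continue_branch,
                         solve_equilibrium)
from .orbits import PeriodicBranch, cycle_from_hopf
from .params import ModelParameters
from .simulate import (Trajectory, default_initial_state, integrate,
                       integrate_system)

DEFAULT_RANGES = {"q": (-0.6, 0.3), "Ca": (0.0, 500.0)}


@dataclass
class FastSubsystemDiagram:
    """Bifurcation structure of the fast subsystem vs a frozen slow variable."""

    frozen_id: str  # "q" | "Ca"
    params: ModelParameters  # drive configuration (ISapp / IDapp)
    branches: list[EquilibriumBranch]
    labels: dict[str, BifurcationPoint]
    po_branch: PeriodicBranch | None = None
    overlay: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def system(self) -> CellSystem:
        return CellSystem(self.params, self.frozen_id)


@dataclass
class BurstClassification:
    initiating: str
    terminating: str
    label: str
    info: dict = field(default_factory=dict)


def _hyperpolarised_eq(system: CellSystem, p: float) -> np.ndarray:
    y0 = default_initial_state(system.params, V=-68.0)
    free = [i for i in range(8)
            if model.STATE_NAMES[i] not in system.frozen]
    traj = integrate_system(system, p, y0[free], t_span=3000.0,
                            rtol=1e-8, atol=1e-8)
    y, _ = solve_equilibrium(system, traj.y[-1], p)
    return y


def _depolarised_eq(system: CellSystem, p: float) -> np.ndarray:
    y0 = default_initial_state(system.params, V=-20.0)
    free = [i for i in range(8)
            if model.STATE_NAMES[i] not in system.frozen]
    traj = integrate_system(system, p, y0[free], t_span=3000.0,
                            rtol=1e-8, atol=1e-8)
    y, _ = solve_equilibrium(system, traj.y[-1], p)
    return y


def build_fast_diagram(params: ModelParameters, frozen_id: str,
                       p_range: tuple[float, float] | None = None,
                       ds_max: float = 0.1) -> FastSubsystemDiagram:
    """Equilibrium skeleton of the fast subsystem with ``frozen_id`` as the
    bifurcation parameter, with the published branch labels attached.

    For the q-diagram the single fold of the hyperpolarised branch is the
    SNIC (the bursting branch of the fast subsystem emerges from it with
    diverging period).  For the Ca-diagram the five folds are labelled
    SN1..SN5 and the subcritical Hopf between SN4 and SN5 is HB, following
    the traversal order of the depolarised branch.
    """
    if frozen_id not in ("q", "Ca"):
        raise ValueError("frozen_id must be 'q' or 'Ca'")
    if p_range is None:
        p_range = DEFAULT_RANGES[frozen_id]
    system = CellSystem(params, frozen_id)
    labels: dict[str, BifurcationPoint] = {}
    branches: list[EquilibriumBranch] = []

    if frozen_id == "q":
        p0 = min(0.3, p_range[1])
        y = _hyperpolarised_eq(system, p0)
        br = continue_branch(system, y, p0, p_range, direction=-1,
                             ds_max=ds_max)
        branches.append(br)
        folds = br.bif("SN")
        if folds:
            snic = folds[0]
            labels["SNIC"] = BifurcationPoint("SNIC", snic.p, snic.y,
                                              snic.diagnostic)
    else:
        p_hi = min(300.0, p_range[1])
        y = _hyperpolarised_eq(system, p_hi)
        lower = continue_branch(system, y, p_hi, p_range, direction=-1,
                                ds_max=ds_max)
        branches.append(lower)
        if lower.bif("SN"):
            labels["SN1"] = lower.bif("SN")[0]
        y_up = _depolarised_eq(system, 50.0)
        upper = continue_branch(system, y_up, 50.0, p_range, direction=+1,
                                ds_max=ds_max, max_points=6000)
        branches.append(upper)
        for i, b in enumerate(upper.bif("SN")):
            labels[f"SN{i + 2}"] = b
        hbs = upper.bif("HB")
        if hbs:
            hb = max(hbs, key=lambda b: b.diagnostic.get("omega", 0.0))
            labels["HB"] = hb
    return FastSubsystemDiagram(frozen_id=frozen_id, params=params,
                                branches=branches, labels=labels,
                                meta={"p_range": tuple(p_range)})


def hopf_is_subcritical(diagram: FastSubsystemDiagram,
                        eps: float = 0.01) -> bool:
    """Check the criticality of the Ca-diagram Hopf numerically: solve the
    small-amplitude emergent cycle and test its Floquet stability."""
    hb = diagram.labels["HB"]
    cyc = cycle_from_hopf(diagram.system, hb, eps=eps, m=24)
    if cyc.stable is None:
        raise ContinuationError("emergent-cycle stability undetermined")
    return not cyc.stable


def overlay_burst(diagram: FastSubsystemDiagram,
                  traj: Trajectory | None = None,
                  t_span: float = 20000.0,
                  transient: float = 5000.0) -> dict:
    """Project a full-system burst onto the (frozen variable, Vs) plane and
    annotate the slow passages.

    For the q-diagram the annotation reports the crossings of the SNIC
    value of q in both directions per burst cycle and the time spent below
    the stable-node branch fold; for the Ca-diagram it reports the Ca range
    against the fold (SN1) and Hopf (HB) values.
    """
    if traj is None:
        traj = integrate(diagram.params, t_span=t_span)
    w = traj.window(transient)
    x = w.column(diagram.frozen_id)
    out = {"t": w.t, "x": x, "Vs": w.vs, "trajectory": w}
    if diagram.frozen_id == "q" and "SNIC" in diagram.labels:
        qsnic = diagram.labels["SNIC"].p
        below = x < qsnic
        down = np.flatnonzero(~below[:-1] & below[1:])
        up = np.flatnonzero(below[:-1] & ~below[1:])
        out.update({
            "snic_value": qsnic,
            "down_crossings": w.t[down],
            "up_crossings": w.t[up],
            "straddles_snic": bool(len(down) > 0 and len(up) > 0),
            "frac_below_snic": float(np.mean(below)),
        })
    if diagram.frozen_id == "Ca":
        out.update({
            "ca_min": float(x.min()), "ca_max": float(x.max()),
            "sn1_value": diagram.labels.get("SN1").p
            if "SN1" in diagram.labels else None,
            "hb_value": diagram.labels.get("HB").p
            if "HB" in diagram.labels else None,
        })
    diagram.overlay = out
    return out


def classify_burster(ca_diagram: FastSubsystemDiagram,
                     overlay: dict | None = None) -> BurstClassification:
    """Classify the burster from the Ca fast-subsystem diagram.

    Initiation: the burst starts when the phase point falls off the fold of
    the hyperpolarised branch (SN1) at low Ca.  Termination: the
    depolarised phase ends around the subcritical Hopf (HB).  The pattern
    yields the fold/subHopf label of the standard bursting taxonomy.
    """
    labels = ca_diagram.labels
    if "SN1" not in labels or "HB" not in labels:
        return BurstClassification(
            "unknown", "unknown", "unclassified",
            {"reason": "fold or Hopf missing from diagram",
             "found": sorted(labels)})
    sub = hopf_is_subcritical(ca_diagram)
    if not sub:
        return BurstClassification(
            "fold", "hopf", "unclassified",
            {"reason": "Hopf is not subcritical"})
    info = {"fold_Ca": labels["SN1"].p, "hopf_Ca": labels["HB"].p,
            "hopf_subcritical": True}
    if overlay is None:
        overlay = ca_diagram.overlay
    if overlay is not None:
        info.update({k: overlay[k] for k in ("ca_min", "ca_max")
                     if k in overlay})
    return BurstClassification("fold", "subHopf", "fold/subHopf", info)


def timescale_separation(params: ModelParameters,
                         vs_range=(-70.0, 20.0), vd_range=(-70.0, 10.0),
                         ca_range=(0.0, 250.0), num=500) -> dict:
    """Gating time-constant extrema over the effective variable ranges.

    The premise of the dissection: tau_h, tau_n (somatic), tau_s, tau_c
    (dendritic) stay below a few ms, while Ca relaxes with 1/0.075 ms and
    tau_q lies in the hundreds of ms.
    """
    vs = np.linspace(*vs_range, num)
    vd = np.linspace(*vd_range, num)
    ca = np.linspace(*ca_range, num)
    out = {
        "tau_h_max": max(model.tau_x("h", v) for v in vs),
        "tau_n_max": max(model.tau_x("n", v) for v in vs),
        "tau_s_max": max(model.tau_x("s", v) for v in vd),
        "tau_c_max": max(model.tau_x("c", v, params.variant) for v in vd),
        "tau_Ca": 1.0 / 0.075,
        "tau_q_min": min(model.tau_x("q", c, params.variant) for c in ca),
        "tau_q_max": max(model.tau_x("q", c, params.variant) for c in ca),
    }
    return out
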