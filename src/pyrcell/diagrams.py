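"""One-parameter bifurcation diagrams with the published point labels.

These builders orchestrate the equilibrium and periodic-orbit machinery
into the complete applied-current diagrams: the S-shaped equilibrium curve
with its folds (SN1, SN2, and for dendritic drive SN3/SN4) and principal
Hopf (HB), the periodic spiking branch with its torus pair (TR1 > TR2 in
the parameter), the period doubling (PD), and the branch-tail termination
(HC or SNIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .dynsys import CellSystem
from .equilibria import (BifurcationPoint, EquilibriumBranch,
                         continue_branch, solve_equilibrium)
from .orbits import (PeriodicBranch, TerminationDiagnostic,
                     classify_termination, continue_cycles,
                     cycle_from_attractor)
from .params import ModelParameters
from .simulate import default_initial_state, integrate


@dataclass
class BifurcationDiagram:
    params: ModelParameters
    bif_param: str
    eq_branch: EquilibriumBranch
    labels: dict[str, BifurcationPoint]
    po_branch: PeriodicBranch | None = None
    termination: TerminationDiagnostic | None = None
    meta: dict = field(default_factory=dict)

    def table(self) -> list[dict]:
        rows = []
        for name, b in sorted(self.labels.items()):
            rows.append({"label": name, "kind": b.kind,
                         "param": self.bif_param, "value": b.p,
                         "Vs": float(b.y[0])})
        if self.termination is not None:
            rows.append({"label": self.termination.kind,
                         "kind": self.termination.kind,
                         "param": self.bif_param,
                         "value": self.termination.p_est,
                         "Vs": float(self.termination.saddle[0])
                         if self.termination.saddle is not None else np.nan})
        return rows


def _start_equilibrium(system: CellSystem, p0: float) -> np.ndarray:
    V = -62.0
    y0 = np.array([V, V, model.x_inf("h", V), model.x_inf("n", V),
                   model.x_inf("s", V), model.x_inf("c", V), 0.06, 0.2])
    y, _ = solve_equilibrium(system, y0, p0)
    return y


def label_equilibrium_bifurcations(
        branch: EquilibriumBranch) -> dict[str, BifurcationPoint]:
    """Name the detected points following the published convention.

    Folds are numbered SN1, SN2, ... in traversal order starting from the
    hyperpolarised branch; the principal Hopf (HB) is the pair crossing
    with the largest angular frequency (the near-fold singular-Hopf
    crossing, when present, has omega three orders of magnitude smaller
    and is reported separately as HB_singular).
    """
    labels: dict[str, BifurcationPoint] = {}
    for i, b in enumerate(branch.bif("SN")):
        labels[f"SN{i + 1}"] = b
    hbs = branch.bif("HB")
    if hbs:
        main = max(hbs, key=lambda b: b.diagnostic.get("omega", 0.0))
        labels["HB"] = main
        rest = [b for b in hbs if b is not main]
        for i, b in enumerate(rest):
            labels["HB_singular" if len(rest) == 1 else f"HB_singular{i + 1}"] = b
    return labels


def equilibrium_diagram(params: ModelParameters, bif_param: str,
                        p_range: tuple[float, float] = (-500.0, 500.0),
                        p_start: float = -1.0, ds_max: float = 0.25,
                        ) -> BifurcationDiagram:
    """Equilibrium curve over ``p_range`` with labelled bifurcations.

    Starts on the hyperpolarised branch (stable node at ``p_start``) and
    traverses the S-curve upward through its folds and Hopf points.
    """
    system = CellSystem(params, bif_param)
    y0 = _start_equilibrium(system, p_start)
    branch = continue_branch(system, y0, p_start, p_range, direction=+1,
                             ds_max=ds_max)
    labels = label_equilibrium_bifurcations(branch)
    return BifurcationDiagram(params=params, bif_param=bif_param,
                              eq_branch=branch, labels=labels,
                              meta={"p_range": tuple(p_range)})


def periodic_diagram(diagram: BifurcationDiagram, start_p: float = 10.0,
                     h0: float = 0.1, max_steps_up: int = 120,
                     max_steps_down: int = 260, period_cap: float = 160.0,
                     p_min: float = -40.0, m: int = 16,
                     classify: bool = True,
                     refine_hc: bool = True) -> BifurcationDiagram:
    """Attach the periodic spiking branch to an equilibrium diagram.

    The branch is seeded from the stable spiking attractor at ``start_p``
    (inside the regular-spiking window between PD and TR2), continued
    upward towards the Hopf (detecting the torus pair) and downward through
    the period doubling into the high-period tail, which is classified as
    HC or SNIC against the SN1 fold.  A homoclinic termination is refined
    by unstable-manifold bisection (``refine_hc``), so a moderate
    ``period_cap`` suffices to identify the limiting saddle.
    """
    params, bif_param = diagram.params, diagram.bif_param
    system = CellSystem(params, bif_param)
    key = {"ISapp": "ISapp", "IDapp": "IDapp"}[bif_param]
    traj = integrate(params.replace(**{key: start_p}), t_span=3000.0)
    cyc = cycle_from_attractor(system, start_p, init=traj.y[-1],
                               t_settle=200.0, m=m, max_period=500.0)
    hb_p = diagram.labels["HB"].p if "HB" in diagram.labels else np.inf
    br_up = continue_cycles(system, cyc, (start_p - 1.0, hb_p + 2.0),
                            direction=+1, h0=h0, h_max=1.0,
                            max_steps=max_steps_up)
    br_dn = continue_cycles(system, cyc, (p_min, start_p + 1.0),
                            direction=-1, h0=h0, max_steps=max_steps_down,
                            period_cap=period_cap)

    cycles = br_up.cycles[::-1] + br_dn.cycles
    bifs = br_up.bifurcations + br_dn.bifurcations
    po = PeriodicBranch(cycles, bifs, meta={"joined_at": start_p})

    def _cluster(bifs, gap=0.05):
        out = []
        for b in sorted(bifs, key=lambda b: -b.p):
            if not out or abs(out[-1].p - b.p) > gap:
                out.append(b)
        return out

    trs = _cluster(po.bif("TR"))
    if len(trs) >= 1:
        diagram.labels["TR1"] = trs[0]
    if len(trs) >= 2:
        diagram.labels["TR2"] = trs[1]
    pds = _cluster(po.bif("PD"))
    if pds:
        diagram.labels["PD"] = pds[0]
        for i, b in enumerate(pds[1:], start=2):
            diagram.labels[f"PD{i}"] = b
    for i, b in enumerate(po.bif("SNP")):
        diagram.labels["SNP" if i == 0 else f"SNP{i + 1}"] = b

    diagram.po_branch = po
    if classify and "SN1" in diagram.labels:
        term = classify_termination(
            system, PeriodicBranch(br_dn.cycles, br_dn.bifurcations),
            diagram.labels["SN1"], refine=refine_hc,
            node_guess=default_initial_state(params))
        diagram.termination = term
        po.termination = term
    return diagram


def full_diagram(params: ModelParameters, bif_param: str,
                 p_range: tuple[float, float] = (-500.0, 500.0),
                 **po_kwargs) -> BifurcationDiagram:
    """Equilibrium diagram plus periodic branch and termination label."""
    d = equilibrium_diagram(params, bif_param, p_range)
    return periodic_diagram(d, **po_kwargs)
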