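"""Two-parameter continuation in the (applied current, gCa) plane.

Saddle-node and Hopf loci are continued as solutions of augmented defining
systems (equilibrium condition plus a null-vector or Hopf-pair condition)
by pseudo-arclength in the plane; a horizontal slice of the resulting
curves at fixed gCa reproduces the one-parameter bifurcation values.

The homoclinic/SNIC locus has no algebraic defining system at this level;
it is traced pointwise by classifying the termination of the periodic
branch tail at sampled gCa values, and the codimension-2 point where the
homoclinic curve meets the SN1 curve (the termination switches from HC to
SNIC) is bracketed by bisection in gCa on the termination label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynsys import CellSystem
from .equilibria import BifurcationPoint, ContinuationError
from .orbits import (TerminationDiagnostic, classify_termination,
                     continue_cycles, cycle_from_attractor)
from .params import THETA_FIELDS, ModelParameters
from .symbolic import dfdp_smooth, jac_smooth, rhs_smooth


@dataclass
class Codim2Curve:
    kind: str  # SN | HB (continued loci) or HC | SNIC (sliced loci)
    I_param: str  # "ISapp" | "IDapp"
    points: list[dict]  # each: {"I":, "gCa":, "y":, ...}
    meta: dict = field(default_factory=dict)

    @property
    def I_values(self) -> np.ndarray:
        return np.array([pt["I"] for pt in self.points])

    @property
    def gca_values(self) -> np.ndarray:
        return np.array([pt["gCa"] for pt in self.points])

    def I_at_gca(self, gca: float) -> float:
        """Interpolated slice of the curve at fixed gCa."""
        g = self.gca_values
        order = np.argsort(g)
        return float(np.interp(gca, g[order], self.I_values[order]))


class _TwoParamCell:
    """Smooth cell vector field as a function of (y, I, gCa)."""

    def __init__(self, params: ModelParameters, I_param: str):
        if I_param not in ("ISapp", "IDapp"):
            raise ValueError("I_param must be ISapp or IDapp")
        self.params = params
        self.I_param = I_param
        self._iI = THETA_FIELDS.index(I_param)
        self._ig = THETA_FIELDS.index("gCa")
        self._theta = list(params.theta())

    def _theta_at(self, I, g):
        th = list(self._theta)
        th[self._iI] = I
        th[self._ig] = g
        return tuple(th)

    def f(self, y, I, g):
        return rhs_smooth(y, self._theta_at(I, g))

    def jac(self, y, I, g):
        return jac_smooth(y, self._theta_at(I, g))

    def dfdI(self, y, I, g):
        return dfdp_smooth(y, self._theta_at(I, g), self.I_param)

    def dfdg(self, y, I, g):
        return dfdp_smooth(y, self._theta_at(I, g), "gCa")


_W8 = np.array([0.01, 0.01, 1.0, 1.0, 1.0, 1.0, 1.0, 0.01])


def _fold_residual(cell, u):
    """Augmented fold system F(u) = 0 with u = (y, v, I, gCa)."""
    y, v, I, g = u[:8], u[8:16], u[16], u[17]
    J = cell.jac(y, I, g)
    return np.concatenate([cell.f(y, I, g), J @ v,
                           [float(np.dot(v, v)) - 1.0]])


def _fold_jacobian(cell, u):
    y, v, I, g = u[:8], u[8:16], u[16], u[17]
    J = cell.jac(y, I, g)
    A = np.zeros((17, 18))
    A[:8, :8] = J
    A[:8, 16] = cell.dfdI(y, I, g)
    A[:8, 17] = cell.dfdg(y, I, g)
    # d(Jv)/dy by central differences on the Jacobian
    for j in range(8):
        h = 1e-5 * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        A[8:16, j] = (cell.jac(yp, I, g) - cell.jac(ym, I, g)) @ v / (2 * h)
    A[8:16, 8:16] = J
    hI = 1e-5 * max(1.0, abs(I))
    A[8:16, 16] = (cell.jac(y, I + hI, g) - cell.jac(y, I - hI, g)) @ v / (2 * hI)
    hg = 1e-5 * max(1.0, abs(g))
    A[8:16, 17] = (cell.jac(y, I, g + hg) - cell.jac(y, I, g - hg)) @ v / (2 * hg)
    A[16, 8:16] = 2 * v
    return A


def _hopf_residual(cell, u):
    """Augmented Hopf system, u = (y, vr, vi, omega, I, gCa)."""
    y, vr, vi = u[:8], u[8:16], u[16:24]
    om, I, g = u[24], u[25], u[26]
    J = cell.jac(y, I, g)
    return np.concatenate([
        cell.f(y, I, g),
        J @ vr + om * vi,
        J @ vi - om * vr,
        [float(np.dot(vr, vr) + np.dot(vi, vi)) - 1.0,
         float(np.dot(vr, vi))],
    ])


def _hopf_jacobian(cell, u):
    y, vr, vi = u[:8], u[8:16], u[16:24]
    om, I, g = u[24], u[25], u[26]
    J = cell.jac(y, I, g)
    A = np.zeros((26, 27))
    A[:8, :8] = J
    A[:8, 25] = cell.dfdI(y, I, g)
    A[:8, 26] = cell.dfdg(y, I, g)
    for j in range(8):
        h = 1e-5 * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        dJ = (cell.jac(yp, I, g) - cell.jac(ym, I, g)) / (2 * h)
        A[8:16, j] = dJ @ vr
        A[16:24, j] = dJ @ vi
    A[8:16, 8:16] = J
    A[8:16, 16:24] = om * np.eye(8)
    A[8:16, 24] = vi
    A[16:24, 8:16] = -om * np.eye(8)
    A[16:24, 16:24] = J
    A[16:24, 24] = -vr
    hI = 1e-5 * max(1.0, abs(I))
    dJI = (cell.jac(y, I + hI, g) - cell.jac(y, I - hI, g)) / (2 * hI)
    A[8:16, 25] = dJI @ vr
    A[16:24, 25] = dJI @ vi
    hg = 1e-5 * max(1.0, abs(g))
    dJg = (cell.jac(y, I, g + hg) - cell.jac(y, I, g - hg)) / (2 * hg)
    A[8:16, 26] = dJg @ vr
    A[16:24, 26] = dJg @ vi
    A[24, 8:16] = 2 * vr
    A[24, 16:24] = 2 * vi
    A[25, 8:16] = vi
    A[25, 16:24] = vr
    return A


def _newton_bordered(residual, jacobian, u0, t_dir, u_ref, ds, scale,
                     tol=1e-9, maxiter=20):
    u = u0.copy()
    for _ in range(maxiter):
        R = residual(u)
        g = float(np.dot(t_dir * scale, (u - u_ref) * scale)) - ds
        res = np.concatenate([R, [g]])
        if np.linalg.norm(res) < tol:
            return u, True
        A = jacobian(u)
        Ab = np.vstack([A, (t_dir * scale * scale)[None, :]])
        try:
            du = np.linalg.solve(Ab, -res)
        except np.linalg.LinAlgError:
            return u, False
        u = u + du
        if not np.all(np.isfinite(u)):
            return u, False
    return u, np.linalg.norm(res) < 1e-6


def _init_fold_vector(cell, y, I, g):
    J = cell.jac(y, I, g)
    ev, V = np.linalg.eig(J)
    k = int(np.argmin(np.abs(ev.real)))
    v = np.real(V[:, k])
    return v / np.linalg.norm(v)


def continue_codim1_in_two_params(params: ModelParameters,
                                  point: BifurcationPoint, I_param: str,
                                  gca_range: tuple[float, float] = (5.0, 12.0),
                                  ds0: float = 0.02, ds_max: float = 0.3,
                                  max_points: int = 2000) -> Codim2Curve:
    """Continue a fold (SN) or Hopf (HB) point in the (I, gCa) plane.

    ``point`` is a converged codim-1 bifurcation found at ``params.gCa``.
    Traversal runs in both gCa directions until ``gca_range`` is covered.
    """
    cell = _TwoParamCell(params, I_param)
    g0 = params.gCa
    I0, y0 = point.p, point.y

    if point.kind in ("SN", "SNIC"):
        v0 = _init_fold_vector(cell, y0, I0, g0)
        u0 = np.concatenate([y0, v0, [I0, g0]])
        residual = lambda u: _fold_residual(cell, u)
        jacobian = lambda u: _fold_jacobian(cell, u)
        scale = np.concatenate([_W8, np.ones(8), [0.02, 0.1]])
        kind = "SN"
    elif point.kind == "HB":
        J = cell.jac(y0, I0, g0)
        ev, V = np.linalg.eig(J)
        om0 = point.diagnostic.get("omega", 1.0)
        k = int(np.argmin(np.abs(ev - 1j * om0)))
        v = V[:, k]
        vr, vi = v.real, v.imag
        # orthonormalise the pair
        nrm = np.sqrt(np.dot(vr, vr) + np.dot(vi, vi))
        vr, vi = vr / nrm, vi / nrm
        u0 = np.concatenate([y0, vr, vi, [abs(ev[k].imag), I0, g0]])
        residual = lambda u: _hopf_residual(cell, u)
        jacobian = lambda u: _hopf_jacobian(cell, u)
        scale = np.concatenate([_W8, np.ones(16), [1.0, 0.02, 0.1]])
        kind = "HB"
    else:
        raise ValueError(f"cannot continue bifurcation kind {point.kind!r}")

    # polish the start point at fixed gCa
    e_g = np.zeros(len(u0))
    e_g[-1] = 1.0
    u0, ok = _newton_bordered(residual, jacobian, u0, e_g, u0, 0.0, scale)
    if not ok:
        raise ContinuationError("codim-2 start point failed to converge")

    points = []

    def record(u):
        points.append({"I": float(u[-2]), "gCa": float(u[-1]),
                       "y": u[:8].copy()})

    record(u0)
    for direction in (-1.0, +1.0):
        u_prev, t_prev = u0.copy(), e_g * direction
        ds = ds0
        for _ in range(max_points // 2):
            # tangent from the bordered Jacobian
            A = jacobian(u_prev)
            Ab = np.vstack([A, (t_prev * scale * scale)[None, :]])
            rhs = np.zeros(Ab.shape[0])
            rhs[-1] = 1.0
            try:
                t = np.linalg.solve(Ab, rhs)
            except np.linalg.LinAlgError:
                break
            t /= np.linalg.norm(t * scale)
            if np.dot(t * scale, t_prev * scale) < 0:
                t = -t
            accepted = False
            while ds >= 1e-8:
                u_new, ok = _newton_bordered(residual, jacobian,
                                             u_prev + ds * t, t, u_prev,
                                             ds, scale)
                if ok:
                    accepted = True
                    break
                ds *= 0.5
            if not accepted:
                warnings.warn(f"codim-2 {kind} curve stalled at "
                              f"gCa={u_prev[-1]:.3f}")
                break
            record(u_new)
            u_prev, t_prev = u_new, t
            ds = min(ds * 1.4, ds_max)
            if not (gca_range[0] <= u_new[-1] <= gca_range[1]):
                break

    points.sort(key=lambda pt: pt["gCa"])
    return Codim2Curve(kind, I_param, points,
                       meta={"gca_range": tuple(gca_range)})


# ---------------------------------------------------------------------------
# termination-type slices and the codim-2 SNIC point
# ---------------------------------------------------------------------------

def termination_at_gca(params: ModelParameters, I_param: str, gca: float,
                       eq_branch_fn, start_I: float = 10.0,
                       period_cap: float = 160.0,
                       max_steps: int = 220) -> TerminationDiagnostic:
    """Classify the periodic-branch termination (HC vs SNIC) at one gCa.

    ``eq_branch_fn(params) -> (sn1, y_attr)`` must supply the SN1 fold point
    and a state in the basin of the stable spiking cycle at ``start_I``.
    """
    pars = params.replace(gCa=float(gca))
    system = CellSystem(pars, I_param)
    sn1, y_attr = eq_branch_fn(pars)
    cyc = cycle_from_attractor(system, start_I, init=y_attr,
                               t_settle=2000.0, m=16, max_period=500.0)
    br = continue_cycles(system, cyc, (-40.0, start_I + 1.0), direction=-1,
                         h0=0.1, max_steps=max_steps, period_cap=period_cap,
                         detect=False)
    return classify_termination(system, br, sn1)


def locate_codim2_snic(params: ModelParameters, I_param: str,
                       eq_branch_fn, gca_lo: float = 7.0,
                       gca_hi: float = 10.0, n_bisect: int = 2,
                       **term_kw) -> dict:
    """Bracket the codimension-2 SNIC point by bisection in gCa.

    The periodic branch terminates in a SNIC at ``gca_lo`` and in a
    homoclinic at ``gca_hi``; each bisection step classifies the
    termination at the interval midpoint and keeps the sub-interval whose
    endpoints disagree.  Returns the final bracket and the terminations
    observed at its endpoints.
    """
    lo = termination_at_gca(params, I_param, gca_lo, eq_branch_fn, **term_kw)
    hi = termination_at_gca(params, I_param, gca_hi, eq_branch_fn, **term_kw)
    if lo.kind != "SNIC" or hi.kind != "HC":
        return {"bracket": (gca_lo, gca_hi), "lo": lo, "hi": hi,
                "converged": False,
                "reason": f"endpoint labels {lo.kind}/{hi.kind} not "
                          f"SNIC/HC"}
    history = [(gca_lo, lo), (gca_hi, hi)]
    for _ in range(n_bisect):
        mid = 0.5 * (gca_lo + gca_hi)
        tm = termination_at_gca(params, I_param, mid, eq_branch_fn, **term_kw)
        history.append((mid, tm))
        if tm.kind == "SNIC":
            gca_lo, lo = mid, tm
        elif tm.kind == "HC":
            gca_hi, hi = mid, tm
        else:
            break
    return {"bracket": (gca_lo, gca_hi), "lo": lo, "hi": hi,
            "converged": True, "history": history,
            "I_estimate": 0.5 * (lo.p_est + hi.p_est)}
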