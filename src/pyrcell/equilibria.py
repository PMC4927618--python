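"""Equilibrium solving, pseudo-arclength continuation and codim-1 detection.

Branches of equilibria are traced with Keller's pseudo-arclength method so
that folds are traversed smoothly.  Two test functions are monitored between
accepted points:

* the sign of ``det J`` (an odd number of real eigenvalues crossing zero —
  generically a saddle-node/fold), combined with a local parameter-direction
  check to label the point ``SN``;
* the number of eigenvalues with positive real part changing by two with a
  genuinely complex pair at the crossing — a Hopf point ``HB``.

Sign changes are refined by bisection along the branch (corrector solves on
secant hyperplanes) to a parameter tolerance of 1e-5 by default.

All routines operate on the system protocol of :mod:`pyrcell.dynsys`, so the
same machinery serves the full 8-D cell model, the fast subsystems with a
frozen slow variable, and simple test systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_RE_TOL = 1e-9  # eigenvalue real-part threshold for the unstable count


class ContinuationError(RuntimeError):
    pass


@dataclass
class BranchPoint:
    p: float
    y: np.ndarray
    eigvals: np.ndarray
    n_unstable: int

    @property
    def stability(self) -> str:
        if self.n_unstable == 0:
            return "stable_node"
        if self.n_unstable < len(self.eigvals):
            return "saddle"
        return "unstable"


@dataclass
class BifurcationPoint:
    kind: str  # SN, HB, SNIC, HC, TR, PD, SNP, codim2_SNIC
    p: float
    y: np.ndarray
    diagnostic: dict = field(default_factory=dict)

    def __repr__(self):
        return f"BifurcationPoint({self.kind}, p={self.p:.6g})"


@dataclass
class EquilibriumBranch:
    points: list[BranchPoint]
    bifurcations: list[BifurcationPoint]
    meta: dict = field(default_factory=dict)

    @property
    def p_values(self) -> np.ndarray:
        return np.array([pt.p for pt in self.points])

    @property
    def states(self) -> np.ndarray:
        return np.array([pt.y for pt in self.points])

    def bif(self, kind: str) -> list[BifurcationPoint]:
        return [b for b in self.bifurcations if b.kind == kind]


def solve_equilibrium(system, guess: np.ndarray, p: float,
                      tol: float = 1e-10, maxiter: int = 60):
    """Damped Newton solve of ``f(y, p) = 0``.

    Returns ``(y, eigvals)``.  Convergence requires the weighted residual to
    drop below ``tol`` or the weighted Newton step below ``1e-12`` (the
    latter covers regimes where a tiny gating time constant inflates one
    residual row far beyond its actual state error).
    """
    y = np.array(guess, dtype=float)
    w = system.weights
    fv = system.f(y, p)
    res = float(np.linalg.norm(w * fv))
    for _ in range(maxiter):
        J = system.jac(y, p)
        try:
            step = np.linalg.solve(J, -fv)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -fv, rcond=None)[0]
        lam = 1.0
        for _ in range(10):
            y_new = y + lam * step
            f_new = system.f(y_new, p)
            res_new = float(np.linalg.norm(w * f_new))
            if res_new < res or res < tol:
                break
            lam *= 0.5
        step_norm = float(np.linalg.norm(w * (y_new - y)))
        y, fv, res = y_new, f_new, res_new
        if res < tol or step_norm < 1e-12:
            if res < max(tol, 1e-6) or step_norm < 1e-12:
                return y, np.linalg.eigvals(system.jac(y, p))
    if res < max(tol * 1e3, 1e-7):
        return y, np.linalg.eigvals(system.jac(y, p))
    raise ContinuationError(
        f"Newton failed to converge at p={p:.6g} (residual {res:.3g})")


def _n_unstable(eigvals: np.ndarray) -> int:
    return int(np.sum(eigvals.real > _RE_TOL))


def _hopf_testfun(eigvals: np.ndarray) -> float:
    """Sign of the product of pairwise eigenvalue sums (bialternate test).

    Changes sign when a complex pair crosses the imaginary axis (Hopf) or
    when two real eigenvalues are symmetric about it (neutral saddle — told
    apart after refinement).  Each factor is normalised to unit modulus so
    only the phase of the product, which determines the sign, is kept.
    """
    lam = eigvals
    terms = []
    n = len(lam)
    for i in range(n):
        for j in range(i + 1, n):
            t = lam[i] + lam[j]
            a = abs(t)
            terms.append(t / a if a > 0 else 0.0)
    z = np.prod(terms)
    return float(np.sign(z.real)) if z != 0 else 0.0


def _closest_pair(eigvals: np.ndarray):
    """Eigenvalue pair minimising |lam_i + lam_j|."""
    n = len(eigvals)
    best, pair = np.inf, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            v = abs(eigvals[i] + eigvals[j])
            if v < best:
                best, pair = v, (i, j)
    return eigvals[pair[0]], eigvals[pair[1]]


def _det_sign(J: np.ndarray) -> float:
    sign, _ = np.linalg.slogdet(J)
    return sign


def _tangent(system, y, p, prev=None):
    """Unit tangent of the branch in the scaled (y, p) metric."""
    n = system.dim
    J = system.jac(y, p)
    b = system.dfdp(y, p)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = J
    A[:n, n] = b
    if prev is None:
        A[n, n] = 1.0
    else:
        A[n, :] = prev
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    try:
        t = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(A, rhs, rcond=None)[0]
    scale = np.concatenate([system.weights, [system.pweight]])
    t_s = t * scale
    t /= np.linalg.norm(t_s)
    if prev is not None and np.dot(t * scale, prev * scale) < 0:
        t = -t
    return t


def _corrector(system, z_pred, t, z_ref, ds, tol=1e-10, maxiter=12):
    """Newton solve of the bordered system on the arclength hyperplane."""
    n = system.dim
    scale = np.concatenate([system.weights, [system.pweight]])
    z = np.array(z_pred, dtype=float)
    for it in range(maxiter):
        y, p = z[:n], z[n]
        fv = system.f(y, p)
        g = float(np.dot(t * scale, (z - z_ref) * scale)) - ds
        res = np.concatenate([fv, [g]])
        res_norm = float(np.linalg.norm(np.append(system.weights * fv, g)))
        if res_norm < tol and it > 0:
            return z, True
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = system.jac(y, p)
        A[:n, n] = system.dfdp(y, p)
        A[n, :] = t * scale * scale
        try:
            dz = np.linalg.solve(A, -res)
        except np.linalg.LinAlgError:
            return z, False
        z = z + dz
        if not np.all(np.isfinite(z)):
            return z, False
        if float(np.linalg.norm(dz * scale)) < 1e-12:
            fv = system.f(z[:n], z[n])
            ok = float(np.linalg.norm(system.weights * fv)) < max(tol, 1e-7)
            return z, ok
    fv = system.f(z[:n], z[n])
    ok = float(np.linalg.norm(system.weights * fv)) < max(tol, 1e-7)
    return z, ok


def _refine_crossing(system, z1, z2, testfun, p_tol=1e-5, max_bisect=80):
    """Bisect a test-function sign change between two nearby branch points.

    ``testfun(y, p, J, eigvals) -> float``;  returns the refined (y, p).
    """
    n = system.dim
    scale = np.concatenate([system.weights, [system.pweight]])

    def _eval(z):
        J = system.jac(z[:n], z[n])
        return testfun(z[:n], z[n], J, np.linalg.eigvals(J))

    s1 = _eval(z1)
    z_lo, z_hi = np.array(z1), np.array(z2)
    for _ in range(max_bisect):
        gap = float(np.linalg.norm((z_hi - z_lo) * scale))
        if gap < 1e-9 and abs(z_hi[n] - z_lo[n]) < p_tol:
            break
        t = (z_hi - z_lo) * scale
        t /= np.linalg.norm(t)
        t_unscaled = t / scale
        zm = 0.5 * (z_lo + z_hi)
        zm, ok = _corrector(system, zm, t_unscaled, zm, 0.0)
        if not ok:
            break
        sm = _eval(zm)
        if sm == 0:
            z_lo = z_hi = zm
            break
        if (sm > 0) == (s1 > 0):
            z_lo = zm
        else:
            z_hi = zm
    zc = 0.5 * (z_lo + z_hi)
    return zc[:n], float(zc[n])


def continue_branch(system, y0: np.ndarray, p0: float,
                    p_range: tuple[float, float], direction: float = 1.0,
                    ds0: float = 0.01, ds_min: float = 1e-6,
                    ds_max: float = 1.0, max_points: int = 20000,
                    detect: bool = True, p_tol: float = 1e-5,
                    stop_after: int | None = None) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium branch.

    Starts from a converged (or convergible) point ``(y0, p0)`` and traces
    the branch in the initial parameter ``direction`` until the parameter
    leaves ``p_range``, the point budget is exhausted, or the step size
    collapses (partial branch + warning).  Detected folds and Hopf points
    are appended to ``branch.bifurcations`` in traversal order.

    ``stop_after`` optionally stops the run once that many bifurcations have
    been found (cheap targeted sweeps).
    """
    n = system.dim
    y, eig = solve_equilibrium(system, y0, p0)
    pts = [BranchPoint(p0, y.copy(), eig, _n_unstable(eig))]
    bifs: list[BifurcationPoint] = []
    t = _tangent(system, y, p0, prev=None)
    if np.sign(t[n]) != np.sign(direction) and t[n] != 0:
        t = -t
    z = np.append(y, p0)
    det_prev = _det_sign(system.jac(y, p0))
    hopf_prev = _hopf_testfun(eig)
    ds = ds0
    warned = False

    for _ in range(max_points):
        accepted = False
        while ds >= ds_min:
            z_pred = z + ds * t
            z_new, ok = _corrector(system, z_pred, t, z, ds)
            if ok:
                accepted = True
                break
            ds *= 0.5
        if not accepted:
            warnings.warn("continuation step collapsed below minimum; "
                          "returning partial branch")
            warned = True
            break

        y_new, p_new = z_new[:n], float(z_new[n])
        J_new = system.jac(y_new, p_new)
        eig_new = np.linalg.eigvals(J_new)
        nu_new = _n_unstable(eig_new)
        det_new = _det_sign(J_new)
        hopf_new = _hopf_testfun(eig_new)

        if detect:
            if det_new * det_prev < 0:
                yb, pb = _refine_crossing(
                    system, z, z_new,
                    lambda yv, pv, J, ev: _det_sign(J), p_tol)
                Jb = system.jac(yb, pb)
                evb = np.linalg.eigvals(Jb)
                zero = evb[np.argmin(np.abs(evb.real))]
                bifs.append(BifurcationPoint(
                    "SN", pb, yb,
                    {"zero_eig": complex(zero),
                     "direction": float(np.sign(z_new[n] - z[n]))}))
            if hopf_new * hopf_prev < 0:
                yb, pb = _refine_crossing(
                    system, z, z_new,
                    lambda yv, pv, J, ev: _hopf_testfun(ev), p_tol)
                evb = np.linalg.eigvals(system.jac(yb, pb))
                l1, l2 = _closest_pair(evb)
                # a genuine Hopf pair is complex conjugate; a neutral saddle
                # (two real eigenvalues symmetric about the axis) is skipped
                if abs(l1.imag) > 1e-5 and abs(l1 - np.conj(l2)) < 1e-5:
                    bifs.append(BifurcationPoint(
                        "HB", pb, yb,
                        {"omega": abs(float(l1.imag)), "pair": complex(l1)}))

        pts.append(BranchPoint(p_new, y_new.copy(), eig_new, nu_new))
        t = _tangent(system, y_new, p_new, prev=t)
        z, det_prev, hopf_prev = z_new, det_new, hopf_new
        ds = min(ds * 1.4, ds_max)

        if stop_after is not None and len(bifs) >= stop_after:
            break
        if not (p_range[0] <= p_new <= p_range[1]):
            break

    return EquilibriumBranch(
        pts, bifs,
        meta={"p_range": p_range, "partial": warned,
              "bif_param": getattr(system, "bif_param", None)})


def detect_fold(system, z1, z2, p_tol: float = 1e-5) -> BifurcationPoint:
    """Refine a fold bracketed by two (y, p) branch points."""
    z1, z2 = np.asarray(z1, dtype=float), np.asarray(z2, dtype=float)
    yb, pb = _refine_crossing(
        system, z1, z2, lambda y, p, J, ev: _det_sign(J), p_tol)
    ev = np.linalg.eigvals(system.jac(yb, pb))
    zero = ev[np.argmin(np.abs(ev.real))]
    if abs(zero.real) > 1e-6:
        warnings.warn(f"fold zero eigenvalue poorly resolved: {zero}")
    return BifurcationPoint("SN", pb, yb, {"zero_eig": complex(zero)})


def detect_hopf(system, z1, z2, p_tol: float = 1e-5) -> BifurcationPoint:
    """Refine a Hopf point bracketed by two (y, p) branch points.

    Raises if the crossing eigenvalues are real (not a Hopf pair).
    """
    z1, z2 = np.asarray(z1, dtype=float), np.asarray(z2, dtype=float)
    yb, pb = _refine_crossing(
        system, z1, z2, lambda y, p, J, ev: _hopf_testfun(ev), p_tol)
    ev = np.linalg.eigvals(system.jac(yb, pb))
    l1, l2 = _closest_pair(ev)
    if abs(l1.imag) < 1e-5 or abs(l1 - np.conj(l2)) > 1e-5:
        raise ContinuationError("crossing eigenvalues are real: not a Hopf")
    return BifurcationPoint("HB", pb, yb,
                            {"omega": abs(float(l1.imag)),
                             "pair": complex(l1)})
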