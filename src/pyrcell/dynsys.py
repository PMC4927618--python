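"""Parameter-dependent dynamical-system interface for the analysis modules.

The continuation and orbit machinery operates on a small protocol:

* ``dim`` — state dimension,
* ``f(y, p)`` — vector field at state ``y`` and bifurcation-parameter value ``p``,
* ``jac(y, p)`` — state Jacobian,
* ``dfdp(y, p)`` — parameter derivative,
* ``weights`` / ``pweight`` — scaling used in arclength metrics and distances
  (voltages and Ca carry weight 1/100 so that mV-scale and gate-scale
  components contribute comparably).

:class:`CellSystem` exposes the smooth pyramidal-cell model (full 8-D system
or a fast subsystem with ``q``/``Ca`` frozen) through this protocol; the
bifurcation parameter may be an applied current, ``gCa``, or a frozen slow
variable.  :class:`CallableSystem` adapts arbitrary callables (used for
cross-checking the machinery on systems with known closed-form behaviour).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .model import IDX, STATE_NAMES, STATE_WEIGHTS
from .params import THETA_FIELDS, ModelParameters
from .symbolic import dfdp_smooth, jac_smooth, rhs_smooth

#: Arclength weight of each supported bifurcation parameter: applied currents
#: and frozen Ca range over O(100), gCa over O(10), frozen q over O(1).
PARAM_WEIGHTS = {"ISapp": 0.02, "IDapp": 0.02, "gCa": 0.1, "q": 1.0, "Ca": 0.02}


class CellSystem:
    """Smooth pyramidal-cell vector field as a one-parameter family.

    Parameters
    ----------
    params:
        Base parameter set (must use the smooth variant).
    bif_param:
        ``"ISapp"``, ``"IDapp"`` or ``"gCa"``, or a slow state variable
        ``"q"``/``"Ca"`` — in the latter case that variable is frozen and its
        value becomes the continuation parameter (fast subsystem).
    frozen:
        Additional slow variables held at fixed values, e.g. ``{"q": 0.1}``.
    """

    def __init__(self, params: ModelParameters, bif_param: str,
                 frozen: dict[str, float] | None = None):
        if params.variant != "smooth":
            raise ValueError("continuation requires the smooth variant")
        if bif_param not in PARAM_WEIGHTS:
            raise ValueError(f"unsupported bifurcation parameter {bif_param!r}")
        self.params = params
        self.bif_param = bif_param
        self.frozen = dict(frozen or {})
        if bif_param in ("q", "Ca"):
            self.frozen[bif_param] = np.nan  # value supplied per-call as p
        if not set(self.frozen) <= {"q", "Ca"}:
            raise ValueError("only q and Ca can be frozen")
        self._free = [i for i in range(8)
                      if STATE_NAMES[i] not in self.frozen]
        self._theta = list(params.theta())
        self._p_in_theta = (THETA_FIELDS.index(bif_param)
                            if bif_param in THETA_FIELDS else None)
        self.dim = len(self._free)
        self.state_names = tuple(STATE_NAMES[i] for i in self._free)
        self.weights = STATE_WEIGHTS[self._free].copy()
        self.pweight = PARAM_WEIGHTS[bif_param]

    def _assemble(self, y: np.ndarray, p: float):
        yf = np.empty(8)
        yf[self._free] = y
        for name, val in self.frozen.items():
            yf[IDX[name]] = val
        theta = list(self._theta)
        if self._p_in_theta is not None:
            theta[self._p_in_theta] = p
        else:
            yf[IDX[self.bif_param]] = p
        return yf, tuple(theta)

    def f(self, y: np.ndarray, p: float) -> np.ndarray:
        yf, theta = self._assemble(y, p)
        return rhs_smooth(yf, theta)[self._free]

    def jac(self, y: np.ndarray, p: float) -> np.ndarray:
        yf, theta = self._assemble(y, p)
        return jac_smooth(yf, theta)[np.ix_(self._free, self._free)]

    def dfdp(self, y: np.ndarray, p: float) -> np.ndarray:
        yf, theta = self._assemble(y, p)
        if self._p_in_theta is not None:
            return dfdp_smooth(yf, theta, self.bif_param)[self._free]
        return jac_smooth(yf, theta)[self._free, IDX[self.bif_param]]

    def full_state(self, y: np.ndarray, p: float) -> np.ndarray:
        """Embed a (possibly reduced) state back into the 8-D phase space."""
        return self._assemble(y, p)[0]

    def at(self, p: float) -> ModelParameters:
        """Parameter set with the bifurcation parameter set to ``p``."""
        if self._p_in_theta is not None:
            return self.params.replace(**{self.bif_param: p})
        return self.params


class CallableSystem:
    """Adapter turning plain callables into the system protocol.

    Missing derivatives fall back to central finite differences.
    """

    def __init__(self, f: Callable, dim: int, jac: Callable | None = None,
                 dfdp: Callable | None = None,
                 weights: np.ndarray | None = None, pweight: float = 1.0):
        self._f = f
        self._jac = jac
        self._dfdp = dfdp
        self.dim = dim
        self.state_names = tuple(f"y{i}" for i in range(dim))
        self.weights = (np.ones(dim) if weights is None
                        else np.asarray(weights, dtype=float))
        self.pweight = pweight

    def f(self, y, p):
        return np.asarray(self._f(np.asarray(y, dtype=float), p), dtype=float)

    def jac(self, y, p):
        if self._jac is not None:
            return np.asarray(self._jac(y, p), dtype=float)
        J = np.empty((self.dim, self.dim))
        h0 = 1e-6
        for j in range(self.dim):
            h = h0 * max(1.0, abs(y[j]))
            yp, ym = np.array(y, dtype=float), np.array(y, dtype=float)
            yp[j] += h
            ym[j] -= h
            J[:, j] = (self.f(yp, p) - self.f(ym, p)) / (2 * h)
        return J

    def dfdp(self, y, p):
        if self._dfdp is not None:
            return np.asarray(self._dfdp(y, p), dtype=float)
        h = 1e-6 * max(1.0, abs(p))
        return (self.f(y, p + h) - self.f(y, p - h)) / (2 * h)
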