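"""Exact Jacobians for the smooth vector field, generated symbolically.

The smooth-variant right-hand side in :mod:`pyrcell.model` is written against
a pluggable math backend, so the very same code path that the integrators
evaluate numerically is traced here with SymPy symbols.  From the traced
expressions we generate fast scalar callables for

* the right-hand side itself (used as the ODE fast path),
* the 8x8 state Jacobian (Newton solves, eigenvalues, variational equations),
* the derivative of the vector field with respect to the continuation
  parameters ISapp, IDapp and gCa.

Generation happens once per process and is cached.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .model import STATE_NAMES, _rhs_scalar
from .params import THETA_FIELDS

_DIFFABLE_PARAMS = ("ISapp", "IDapp", "gCa")


@lru_cache(maxsize=1)
def _build():
    y = sp.symbols(" ".join(STATE_NAMES), real=True)
    th = sp.symbols(" ".join(THETA_FIELDS), real=True, positive=False)
    f = _rhs_scalar(list(y), list(th), "smooth", mt=sp)
    fmat = sp.Matrix(f)
    jac = fmat.jacobian(y)
    args = list(y) + list(th)

    f_fn = sp.lambdify(args, f, modules="math", cse=False)
    jac_fn = sp.lambdify(args, [jac[i, j] for i in range(8) for j in range(8)],
                         modules="math", cse=False)
    dfdp_fns = {
        name: sp.lambdify(args, [e.diff(th[THETA_FIELDS.index(name)])
                                 for e in f], modules="math", cse=False)
        for name in _DIFFABLE_PARAMS
    }
    return f_fn, jac_fn, dfdp_fns


def rhs_smooth(y: np.ndarray, theta: tuple) -> np.ndarray:
    """Fast smooth-variant right-hand side (generated code).

    Overflow at wildly unphysical states (diverged Newton trial steps)
    degrades to NaN so callers can back off.
    """
    f_fn, _, _ = _build()
    try:
        return np.array(f_fn(*y, *theta))
    except OverflowError:
        return np.full(8, np.nan)


def jac_smooth(y: np.ndarray, theta: tuple) -> np.ndarray:
    """Exact 8x8 state Jacobian of the smooth right-hand side."""
    _, jac_fn, _ = _build()
    try:
        return np.array(jac_fn(*y, *theta)).reshape(8, 8)
    except OverflowError:
        return np.full((8, 8), np.nan)


def dfdp_smooth(y: np.ndarray, theta: tuple, param: str) -> np.ndarray:
    """Exact derivative of the right-hand side w.r.t. one theta parameter."""
    _, _, dfdp_fns = _build()
    if param not in dfdp_fns:
        raise ValueError(f"no symbolic parameter derivative for {param!r}")
    try:
        return np.array(dfdp_fns[param](*y, *theta))
    except OverflowError:
        return np.full(8, np.nan)
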