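"""Two-compartment pyramidal cell model: gating kinetics, currents, right-hand sides.

The model couples an axosomatic compartment (transient Na, delayed-rectifier K,
leak) to a dendritic compartment (persistent Ca, Ca-activated K, slow AHP K,
leak) through an ohmic coupling conductance.  The state is the 8-vector

    (Vs, Vd, h, n, s, c, q, Ca)

with membrane potentials in mV, gating variables dimensionless and
intracellular calcium dimensionless; time is measured in ms.  The Na
activation gate ``m`` is instantaneous: the sodium current uses
``m_inf(Vs)**2`` directly and ``m`` is not a state variable.

Two kinetic variants are provided.  The ``original`` variant uses the
historical discontinuous rate functions for ``c``, ``q`` and the
Ca-saturation function ``chi`` (Heaviside switch at Vd = -10 mV, hard ``min``
caps).  The ``smooth`` variant replaces those three pieces by fully
continuous fitted curves (a sharp-sigmoid power for c_inf, single/double
exponentials for tau_c, q_inf, tau_q and a three-term sine series for chi)
so that the vector field is differentiable everywhere — the property the
continuation machinery in :mod:`pyrcell.equilibria` and :mod:`pyrcell.orbits`
relies on.  The rate functions for m, h, n, s are continuous already and are
shared by both variants.

All scalar kinetics helpers accept a ``mt`` (math backend) argument so the
same code path can be traced symbolically (see :mod:`pyrcell.symbolic`) to
generate exact Jacobians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from .params import ModelParameters

STATE_NAMES = ("Vs", "Vd", "h", "n", "s", "c", "q", "Ca")
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Weights used for scaled norms/distances in the analysis modules:
#: voltages (and Ca, which reaches O(100)) are scaled by 1/100.
STATE_WEIGHTS = np.array([0.01, 0.01, 1.0, 1.0, 1.0, 1.0, 1.0, 0.01])

_EXP_CAP = 50.0  # |argument| above which exp-based forms use their asymptote


def _is_sym(x: Any) -> bool:
    return not isinstance(x, (int, float, np.floating))


def _linexpm1(a: float, x: Any, b: float, mt=math) -> Any:
    """``a*x / (exp(x/b) - 1)`` with the removable singularity at x = 0 filled.

    For |x/b| beyond the overflow guard the exact asymptotes are used
    (``a*x*exp(-x/b)`` for large positive argument, ``-a*x`` for large
    negative), which agree with the full form to double precision.
    """
    u = x / b
    if not _is_sym(x):
        if u > _EXP_CAP:
            return a * x * mt.exp(-u)
        if u < -_EXP_CAP:
            return -a * x
        if abs(u) < 1e-7:
            return a * b * (1.0 - u / 2.0 + u * u / 12.0)
        return a * x / (mt.exp(u) - 1.0)
    sp = mt
    return sp.Piecewise(
        (a * x * sp.exp(-u), u > _EXP_CAP),
        (-a * x, u < -_EXP_CAP),
        (a * b * (1 - u / 2 + u * u / 12), sp.Abs(u) < 1e-7),
        (a * x / (sp.exp(u) - 1), True),
    )


def _sigmoid(z: Any, mt=math) -> Any:
    """Overflow-safe logistic ``1/(1+exp(-z))``."""
    if not _is_sym(z):
        if z >= 0:
            return 1.0 / (1.0 + mt.exp(-min(z, 700.0)))
        ez = mt.exp(max(z, -700.0))
        return ez / (1.0 + ez)
    sp = mt
    return sp.Piecewise(
        (1 / (1 + sp.exp(-z)), z >= 0),
        (sp.exp(z) / (1 + sp.exp(z)), True),
    )


def _softplus(z: Any, mt=math) -> Any:
    """Overflow-safe ``log(1+exp(z))``."""
    if not _is_sym(z):
        if z > _EXP_CAP:
            return z
        if z < -_EXP_CAP:
            return mt.exp(z)
        return mt.log(1.0 + mt.exp(z))
    sp = mt
    return sp.Piecewise(
        (z, z > _EXP_CAP),
        (sp.exp(z), z < -_EXP_CAP),
        (sp.log(1 + sp.exp(z)), True),
    )


# ---------------------------------------------------------------------------
# rate functions (alpha/beta form); m, h, n, s are shared by both variants
# ---------------------------------------------------------------------------

def alpha_m(Vs, mt=math):
    return _linexpm1(0.32, -46.9 - Vs, 4.0, mt)


def beta_m(Vs, mt=math):
    return _linexpm1(0.28, Vs + 19.9, 5.0, mt)


def alpha_n(Vs, mt=math):
    return _linexpm1(0.016, -24.9 - Vs, 5.0, mt)


def beta_n(Vs, mt=math):
    return 0.25 * mt.exp(-1.0 - 0.025 * Vs)


def alpha_h(Vs, mt=math):
    return 0.128 * mt.exp((-43.0 - Vs) / 18.0)


def beta_h(Vs, mt=math):
    return 4.0 * _sigmoid((Vs + 20.0) / 5.0, mt)


def alpha_s(Vd, mt=math):
    return 1.6 * _sigmoid(0.072 * (Vd - 5.0), mt)


def beta_s(Vd, mt=math):
    return _linexpm1(0.02, Vd + 8.9, 5.0, mt)


def alpha_c_original(Vd, mt=math):
    # Heaviside switch at Vd = -10 exactly as in the historical formulation.
    if Vd <= -10.0:
        return mt.exp((Vd + 50.0) / 11.0 - (Vd + 53.5) / 27.0) / 18.975
    return 2.0 * mt.exp((-53.5 - Vd) / 27.0)


def beta_c_original(Vd, mt=math):
    if Vd <= -10.0:
        return 2.0 * mt.exp((-53.5 - Vd) / 27.0) - alpha_c_original(Vd, mt)
    return 0.0


def alpha_q_original(Ca, mt=math):
    return min(0.00002 * Ca, 0.01)


def beta_q_original(Ca, mt=math):
    return 0.001


_RATES: dict[str, tuple[Callable, Callable]] = {
    "m": (alpha_m, beta_m),
    "n": (alpha_n, beta_n),
    "h": (alpha_h, beta_h),
    "s": (alpha_s, beta_s),
    "c_orig": (alpha_c_original, beta_c_original),
    "q_orig": (alpha_q_original, beta_q_original),
}


def gating_rate(gate_id: str, U: float) -> tuple[float, float]:
    """Forward/backward rates (1/ms) of a gate at membrane potential or Ca ``U``.

    ``gate_id`` is one of ``m, n, h, s`` (voltage, shared by both variants)
    or ``c_orig, q_orig`` (the discontinuous original-variant kinetics, as a
    function of Vd and Ca respectively).  Steady state and time constant
    follow as ``x_inf = a/(a+b)`` and ``tau = 1/(a+b)``.
    """
    if not math.isfinite(U):
        raise ValueError("gating_rate requires a finite argument")
    try:
        fa, fb = _RATES[gate_id]
    except KeyError:
        raise ValueError(
            f"unknown gate_id {gate_id!r}; expected one of {sorted(_RATES)}"
        ) from None
    return float(fa(U)), float(fb(U))


# ---------------------------------------------------------------------------
# smooth fitted kinetics for c, q and the chi saturation function
# ---------------------------------------------------------------------------

def c_inf_smooth(Vd, mt=math):
    # ((1 + exp((-10.1 - Vd)/0.1016))**-1)**0.00925, evaluated in log space
    # because the inner exponential overflows for Vd below about -82 mV.
    z = (-10.1 - Vd) / 0.1016
    return mt.exp(-0.00925 * _softplus(z, mt))


def tau_c_smooth(Vd, mt=math):
    return 3.627 * mt.exp(0.03704 * Vd)


def q_inf_smooth(Ca, mt=math):
    return 0.7894 * mt.exp(0.0002726 * Ca) - 0.7292 * mt.exp(-0.01672 * Ca)


def tau_q_smooth(Ca, mt=math):
    return 657.9 * mt.exp(-0.02023 * Ca) + 301.8 * mt.exp(-0.002381 * Ca)


def chi_smooth(Ca, mt=math):
    return (
        1.073 * mt.sin(0.003453 * Ca + 0.08095)
        + 0.08408 * mt.sin(0.01634 * Ca - 2.34)
        + 0.01811 * mt.sin(0.0348 * Ca - 0.9918)
    )


def chi_original(Ca, mt=math):
    return min(Ca / 250.0, 1.0)


def chi(Ca: float, variant: str = "smooth") -> float:
    """Ca saturation factor of the Ca-activated K current."""
    if variant == "smooth":
        return float(chi_smooth(Ca))
    return float(chi_original(Ca))


def smooth_gate(gate_id: str, U: float) -> tuple[float, float]:
    """Fitted (x_inf, tau) of the smooth-variant ``c`` (vs Vd) or ``q`` (vs Ca)."""
    if gate_id == "c":
        return float(c_inf_smooth(U)), float(tau_c_smooth(U))
    if gate_id == "q":
        return float(q_inf_smooth(U)), float(tau_q_smooth(U))
    raise ValueError("smooth_gate expects gate_id 'c' or 'q'")


def x_inf(gate_id: str, U: float, variant: str = "smooth") -> float:
    """Steady-state activation of any gate in the requested variant."""
    if variant == "smooth" and gate_id in ("c", "q"):
        return smooth_gate(gate_id, U)[0]
    key = gate_id + "_orig" if gate_id in ("c", "q") else gate_id
    a, b = gating_rate(key, U)
    return a / (a + b)


def tau_x(gate_id: str, U: float, variant: str = "smooth") -> float:
    """Time constant (ms) of any gate in the requested variant."""
    if variant == "smooth" and gate_id in ("c", "q"):
        return smooth_gate(gate_id, U)[1]
    key = gate_id + "_orig" if gate_id in ("c", "q") else gate_id
    a, b = gating_rate(key, U)
    return 1.0 / (a + b)


# ---------------------------------------------------------------------------
# currents and right-hand sides
# ---------------------------------------------------------------------------

@dataclass
class CurrentBreakdown:
    """Instantaneous membrane and coupling currents (model units)."""

    INa: float
    IKDR: float
    ICa: float
    IKCa: float
    IKAHP: float
    ISD: float
    IDS: float
    ILeak_s: float
    ILeak_d: float


def m_inf(Vs, mt=math):
    am = alpha_m(Vs, mt)
    return am / (am + beta_m(Vs, mt))


def ionic_currents(state: np.ndarray, params: ModelParameters) -> CurrentBreakdown:
    """Evaluate every membrane current at ``state``.

    The Na current uses the instantaneous activation ``m_inf(Vs)**2``; the
    Ca-activated K current carries the product ``c * chi(Ca)``.  The coupling
    currents satisfy ``ISD = -IDS = gC (Vd - Vs)`` identically.
    """
    Vs, Vd, h, n, s, c, q, Ca = (float(v) for v in state)
    pr = params
    INa = pr.gNa * m_inf(Vs) ** 2 * h * (Vs - pr.VNa)
    IKDR = pr.gKDR * n * (Vs - pr.VK)
    ICa = pr.gCa * s * s * (Vd - pr.VCa)
    IKCa = pr.gKCa * c * chi(Ca, pr.variant) * (Vd - pr.VK)
    IKAHP = pr.gKAHP * q * (Vd - pr.VK)
    ISD = pr.gC * (Vd - Vs)
    return CurrentBreakdown(
        INa=INa, IKDR=IKDR, ICa=ICa, IKCa=IKCa, IKAHP=IKAHP,
        ISD=ISD, IDS=-ISD,
        ILeak_s=pr.gL * (Vs - pr.VL),
        ILeak_d=pr.gL * (Vd - pr.VL),
    )


def _rhs_scalar(y, theta, variant: str, mt=math) -> list:
    """Backend-generic right-hand side; ``y`` is the 8-component state.

    Note on the coupling sign: the breakdown current ``ISD = gC (Vd - Vs)``
    flows from dendrite to soma, so it enters the somatic balance with ``+``
    and the dendritic balance with ``-`` — equivalently the dendrite receives
    ``gC (Vs - Vd)/(1-p)``, the charge-conserving form of the original
    two-compartment model.
    """
    Vs, Vd, h, n, s, c, q, Ca = y
    (gNa, gKDR, gKCa, gKAHP, gCa, gL, gC,
     VNa, VK, VCa, VL, p, Cm, ISapp, IDapp) = theta

    am = alpha_m(Vs, mt)
    minf = am / (am + beta_m(Vs, mt))
    INa = gNa * minf * minf * h * (Vs - VNa)
    IKDR = gKDR * n * (Vs - VK)
    ICa = gCa * s * s * (Vd - VCa)
    IKAHP = gKAHP * q * (Vd - VK)
    Isd = gC * (Vd - Vs)

    if variant == "smooth":
        IKCa = gKCa * c * chi_smooth(Ca, mt) * (Vd - VK)
        cinf, tauc = c_inf_smooth(Vd, mt), tau_c_smooth(Vd, mt)
        qinf, tauq = q_inf_smooth(Ca, mt), tau_q_smooth(Ca, mt)
        dc = (cinf - c) / tauc
        dq = (qinf - q) / tauq
    else:
        IKCa = gKCa * c * chi_original(Ca, mt) * (Vd - VK)
        ac, bc = alpha_c_original(Vd, mt), beta_c_original(Vd, mt)
        aq, bq = alpha_q_original(Ca, mt), beta_q_original(Ca, mt)
        dc = ac * (1.0 - c) - bc * c
        dq = aq * (1.0 - q) - bq * q

    dVs = (-gL * (Vs - VL) - INa - IKDR + Isd / p + ISapp / p) / Cm
    dVd = (-gL * (Vd - VL) - ICa - IKCa - IKAHP - Isd / (1.0 - p)
           + IDapp / (1.0 - p)) / Cm

    ah, bh = alpha_h(Vs, mt), beta_h(Vs, mt)
    an, bn = alpha_n(Vs, mt), beta_n(Vs, mt)
    as_, bs = alpha_s(Vd, mt), beta_s(Vd, mt)
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    ds = as_ * (1.0 - s) - bs * s
    dCa = -0.13 * ICa - 0.075 * Ca
    return [dVs, dVd, dh, dn, ds, dc, dq, dCa]


def rhs_full(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative of the full 8-dimensional state."""
    y = np.asarray(state, dtype=float)
    if y.shape != (8,) or not np.all(np.isfinite(y)):
        raise ValueError("state must be a finite 8-component vector")
    return np.array(_rhs_scalar([float(v) for v in y], params.theta(),
                                params.variant))


def rhs_fast(fast_state: np.ndarray, frozen: dict[str, float],
             params: ModelParameters) -> np.ndarray:
    """Right-hand side of the fast subsystem with ``q`` and/or ``Ca`` frozen.

    ``frozen`` maps a subset of {"q", "Ca"} to fixed values; the frozen
    components are treated as parameters (their derivatives are removed) and
    the remaining state keeps the full-system dynamics.
    """
    if not frozen or not set(frozen) <= {"q", "Ca"}:
        raise ValueError("frozen must fix at least one of 'q' and 'Ca'")
    free = [i for i in range(8) if STATE_NAMES[i] not in frozen]
    yf = np.asarray(fast_state, dtype=float)
    if yf.shape != (len(free),) or not np.all(np.isfinite(yf)):
        raise ValueError(
            f"fast state must be a finite {len(free)}-component vector"
        )
    y = np.empty(8)
    y[free] = yf
    for name, val in frozen.items():
        y[IDX[name]] = float(val)
    return rhs_full(y, params)[free]


# ---------------------------------------------------------------------------
# smooth-vs-original approximation error (validation of the fitted kinetics)
# ---------------------------------------------------------------------------

def approximation_error(
    vd_range: tuple[float, float] = (-100.0, 50.0),
    ca_range: tuple[float, float] = (0.0, 500.0),
    num: int = 2001,
) -> dict[str, dict[str, np.ndarray]]:
    """Error of each fitted function against its discontinuous original.

    Relative error is reported for the time constants tau_c and tau_q;
    absolute error for c_inf, q_inf and chi.  Returns, per function, the
    evaluation grid, both curves and the error curve.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    vd = np.linspace(*vd_range, num)
    ca = np.linspace(*ca_range, num)

    def _tab(name, grid, f_orig, f_smooth, relative):
        orig = np.array([f_orig(u) for u in grid])
        fit = np.array([f_smooth(u) for u in grid])
        err = np.abs(fit - orig)
        if relative:
            err = err / np.abs(orig)
        out[name] = {"grid": grid, "original": orig, "smooth": fit, "error": err}

    def cinf_o(u):
        a, b = alpha_c_original(u), beta_c_original(u)
        return a / (a + b)

    def tauc_o(u):
        a, b = alpha_c_original(u), beta_c_original(u)
        return 1.0 / (a + b)

    def qinf_o(u):
        a, b = alpha_q_original(u), beta_q_original(u)
        return a / (a + b)

    def tauq_o(u):
        a, b = alpha_q_original(u), beta_q_original(u)
        return 1.0 / (a + b)

    _tab("c_inf", vd, cinf_o, c_inf_smooth, relative=False)
    _tab("tau_c", vd, tauc_o, tau_c_smooth, relative=True)
    _tab("q_inf", ca, qinf_o, q_inf_smooth, relative=False)
    _tab("tau_q", ca, tauq_o, tau_q_smooth, relative=True)
    _tab("chi", ca, chi_original, chi_smooth, relative=False)
    return out
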