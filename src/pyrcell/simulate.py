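"""Time integration, spike/burst detection, firing-pattern classification,
f/I curves and the Ca--Vd phase analysis of the singlet-to-doublet transition.

The model mixes sub-millisecond spike upstrokes with interburst intervals of
seconds, so a stiff error-controlled integrator (LSODA with the exact state
Jacobian for the smooth variant) is used throughout, with absolute/relative
tolerances of 1e-8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import model
from .params import ModelParameters
from .symbolic import jac_smooth, rhs_smooth

FIRING_LABELS = (
    "hyperpolarised_rest", "depolarised_rest", "regular_spiking",
    "waxing_waning", "doublets", "aperiodic", "vlf_bursting",
)


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time course of the model state with solver metadata."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), dim)
    params: ModelParameters
    meta: dict = field(default_factory=dict)

    @property
    def vs(self) -> np.ndarray:
        return self.y[:, 0]

    def column(self, name: str) -> np.ndarray:
        return self.y[:, model.IDX[name]]

    def window(self, t_from: float, t_to: float | None = None) -> "Trajectory":
        m = self.t >= t_from
        if t_to is not None:
            m &= self.t <= t_to
        return Trajectory(self.t[m], self.y[m], self.params, dict(self.meta))


def default_initial_state(params: ModelParameters | None = None,
                          V: float = -65.0) -> np.ndarray:
    """Package default initial condition: both compartments at ``V`` with
    gates at steady state, a small q and near-zero Ca.  (The source figures
    do not state their initial conditions; this default is our own and is
    only meant to land in the attractor's basin.)"""
    variant = params.variant if params is not None else "smooth"
    return np.array([
        V, V,
        model.x_inf("h", V), model.x_inf("n", V), model.x_inf("s", V),
        model.x_inf("c", V, variant), 0.1, 0.2,
    ])


def integrate(params: ModelParameters, init: np.ndarray | None = None,
              t_span: float | tuple[float, float] = 2000.0,
              rtol: float = 1e-8, atol: float = 1e-8,
              t_eval: np.ndarray | None = None,
              max_step: float = np.inf, dense: bool = False) -> Trajectory:
    """Integrate the full model.  ``t_span`` may be a duration or (t0, t1)."""
    if np.isscalar(t_span):
        t_span = (0.0, float(t_span))
    if t_span[1] <= t_span[0]:
        raise ValueError("t_span must have positive duration")
    y0 = default_initial_state(params) if init is None else np.asarray(
        init, dtype=float)
    if y0.shape != (8,) or not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be a finite 8-vector")

    theta = params.theta()
    if params.variant == "smooth":
        def rhs(t, y):
            return rhs_smooth(y, theta)

        def jac(t, y):
            return jac_smooth(y, theta)
    else:
        def rhs(t, y):
            return model._rhs_scalar(list(y), theta, "original")

        jac = None

    sol = solve_ivp(rhs, t_span, y0, method="LSODA", jac=jac,
                    rtol=rtol, atol=atol, t_eval=t_eval,
                    max_step=max_step, dense_output=dense)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.6g} ms: {sol.message}")
    meta = {"rtol": rtol, "atol": atol, "method": "LSODA"}
    traj = Trajectory(sol.t, sol.y.T, params, meta)
    if dense:
        traj.meta["sol"] = sol.sol
    return traj


def integrate_system(system, p: float, init: np.ndarray,
                     t_span: float | tuple[float, float] = 2000.0,
                     rtol: float = 1e-8, atol: float = 1e-8,
                     t_eval: np.ndarray | None = None) -> Trajectory:
    """Integrate a (possibly reduced) system from :mod:`pyrcell.dynsys`."""
    if np.isscalar(t_span):
        t_span = (0.0, float(t_span))
    sol = solve_ivp(lambda t, y: system.f(y, p), t_span,
                    np.asarray(init, dtype=float), method="LSODA",
                    jac=lambda t, y: system.jac(y, p),
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.6g} ms: {sol.message}")
    return Trajectory(sol.t, sol.y.T, system.at(p),
                      {"rtol": rtol, "atol": atol, "system": system, "p": p})


# ---------------------------------------------------------------------------
# spikes, events and firing-pattern classification
# ---------------------------------------------------------------------------

def detect_spikes(traj: Trajectory, threshold: float = -10.0,
                  column: str = "Vs") -> np.ndarray:
    """Times of upward crossings of ``Vs`` through ``threshold``.

    Crossing times are refined by linear interpolation between the solver's
    own (adaptive, hence spike-resolving) output points.
    """
    v = traj.column(column)
    t = traj.t
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if len(idx) == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _auto_isi_threshold(isi: np.ndarray) -> float | None:
    """Otsu-style two-cluster split of the log inter-spike intervals.

    Returns the geometric-mean threshold between the clusters, or None when
    the distribution does not separate (unimodal tonic spiking).
    """
    if len(isi) < 2:
        return None
    x = np.sort(np.log(np.maximum(isi, 1e-6)))
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    best, kbest = -np.inf, None
    for k in range(1, n):
        m1 = csum[k - 1] / k
        m2 = (total - csum[k - 1]) / (n - k)
        var_between = k * (n - k) * (m1 - m2) ** 2
        if var_between > best:
            best, kbest = var_between, k
    lo, hi = x[:kbest], x[kbest:]
    ratio = np.exp(hi.mean() - lo.mean())
    if ratio < 2.0 or np.exp(lo.max()) > 50.0:
        return None
    return float(np.exp(0.5 * (lo.max() + hi.min())))


def group_events(spike_times: np.ndarray,
                 isi_group: float | str = 25.0) -> list[np.ndarray]:
    """Group spikes separated by less than ``isi_group`` ms into one event
    (an event with two or more spikes is a burst).

    With ``isi_group="auto"`` the threshold is derived from the inter-spike
    interval distribution itself: the log-ISIs are split into two clusters
    at the point maximising the between-class variance (Otsu's criterion);
    the split is kept only if the clusters are well separated (geometric
    mean ratio >= 2, short cluster below 50 ms), otherwise the distribution
    is treated as unimodal tonic spiking and no grouping is applied.  This
    keeps intraburst intervals of a few ms separate from fast tonic spiking
    whose period can itself be below any fixed threshold.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) == 0:
        return []
    isi = np.diff(spike_times)
    if isinstance(isi_group, str):
        if isi_group != "auto":
            raise ValueError("isi_group must be a float or 'auto'")
        thr = _auto_isi_threshold(isi)
        if thr is None:
            return [np.array([s]) for s in spike_times]
    else:
        thr = float(isi_group)
    cuts = np.flatnonzero(isi >= thr) + 1
    return np.split(spike_times, cuts)


@dataclass
class FiringPattern:
    label: str
    spike_times: np.ndarray
    events: list[np.ndarray]
    event_type: str  # spike | burst | mixed | none
    mean_frequency: float  # events per second

    def __post_init__(self):
        assert self.label in FIRING_LABELS or self.label.endswith("_rest")


def _event_is_burst(event: np.ndarray, traj: Trajectory,
                    vd_burst: float = 0.0) -> bool:
    """An event is a burst if it has several somatic spikes or rides a full
    dendritic Ca spike (Vd exceeding ``vd_burst``) — the latter catches
    bursts whose later somatic spikelets stay below the spike threshold."""
    if len(event) >= 2:
        return True
    m = (traj.t >= event[0] - 5.0) & (traj.t <= event[-1] + 30.0)
    vd = traj.column("Vd")[m]
    return len(vd) > 0 and float(vd.max()) > vd_burst


def event_types(events: list[np.ndarray], traj: Trajectory | None = None,
                vd_burst: float = 0.0) -> str:
    """Overall event class: ``spike``, ``burst``, ``mixed`` or ``none``."""
    if not events:
        return "none"
    if traj is None:
        flags = [len(e) >= 2 for e in events]
    else:
        flags = [_event_is_burst(e, traj, vd_burst) for e in events]
    if all(flags):
        return "burst"
    if any(flags):
        return "mixed"
    return "spike"


def classify_firing(traj: Trajectory, transient: float = 2000.0,
                    threshold: float = -10.0,
                    isi_group: float | str = "auto",
                    rest_range: float = 1.0, rest_split: float = -45.0,
                    amp_mod: float = 10.0, cv_regular: float = 0.05,
                    vlf_interburst: float = 500.0,
                    vd_burst: float = 0.0) -> FiringPattern:
    """Assign a firing-pattern label to the post-transient trajectory.

    Decision rules (all thresholds configurable):

    * Vs range < ``rest_range`` mV over the final second -> rest, split into
      hyperpolarised/depolarised at ``rest_split`` mV;
    * fast continuous spiking (median ISI < 15 ms, no gap above 100 ms)
      whose spike-peak envelope undulates by more than ``amp_mod`` mV
      -> waxing_waning;
    * all events bursts (several spikes, or a single spike riding a full
      dendritic Ca spike with Vd > ``vd_burst``): inter-event interval above
      ``vlf_interburst`` ms -> vlf_bursting; periodic two-spike events in
      close succession -> doublets; otherwise aperiodic;
    * all events single spikes: period-2 alternation of the inter-spike
      interval -> doublets; near-constant intervals (CV < ``cv_regular``)
      with a flat envelope -> regular_spiking; otherwise aperiodic;
    * anything else (mixed, chaotic) -> aperiodic.
    """
    w = traj.window(transient)
    if len(w.t) < 10:
        raise ValueError("trajectory too short for the requested transient")
    spikes = detect_spikes(w, threshold)
    tail = w.window(w.t[-1] - 1000.0)
    vs_range = float(tail.vs.max() - tail.vs.min())
    if len(spikes) < 3 and vs_range < rest_range:
        level = float(np.median(tail.vs))
        label = ("hyperpolarised_rest" if level < rest_split
                 else "depolarised_rest")
        return FiringPattern(label, spikes, [], "none", 0.0)

    events = group_events(spikes, isi_group)
    etype = event_types(events, w, vd_burst)
    duration_s = (w.t[-1] - w.t[0]) / 1000.0
    freq = len(events) / duration_s if duration_s > 0 else 0.0
    if len(events) < 3:
        return FiringPattern("aperiodic", spikes, events, etype, freq)

    isi = np.diff(spikes)
    idx = np.searchsorted(w.t, spikes)
    peaks = np.array([w.vs[max(0, i - 5): i + 25].max() for i in idx])
    envelope = float(peaks.max() - peaks.min())

    # period-2 alternation of the inter-spike interval marks the
    # period-doubled (doublet) regime; test it before the envelope rule
    # because the alternating spikes also alternate in height
    if etype == "spike" and len(isi) >= 6:
        a, b = isi[::2], isi[1::2]
        sep = abs(a.mean() - b.mean()) / isi.mean()
        within = max(a.std() / a.mean(), b.std() / b.mean())
        if sep > 0.1 and within < 0.05:
            return FiringPattern("doublets", spikes, events, etype, freq)

    if (envelope >= amp_mod and float(np.median(isi)) < 15.0
            and float(isi.max()) < 100.0):
        return FiringPattern("waxing_waning", spikes, events, etype, freq)

    starts = np.array([e[0] for e in events])
    iei = np.diff(starts)

    if etype == "burst":
        if np.mean(iei) > vlf_interburst:
            return FiringPattern("vlf_bursting", spikes, events, etype, freq)
        sizes = {len(e) for e in events}
        if (sizes == {2} and np.mean(iei) < 200.0
                and float(np.std(iei) / np.mean(iei)) < 0.1):
            return FiringPattern("doublets", spikes, events, etype, freq)
        return FiringPattern("aperiodic", spikes, events, etype, freq)

    if etype == "spike" and len(isi) >= 3:
        cv = float(np.std(isi) / np.mean(isi))
        if cv < cv_regular and envelope < amp_mod:
            return FiringPattern("regular_spiking", spikes, events,
                                 etype, freq)
    return FiringPattern("aperiodic", spikes, events, etype, freq)


# ---------------------------------------------------------------------------
# f/I curves
# ---------------------------------------------------------------------------

def fi_curve(params: ModelParameters, I_values: np.ndarray,
             compartment: str = "soma", t_settle: float = 3000.0,
             t_measure: float = 5000.0, threshold: float = -10.0,
             isi_group: float | str = "auto", rtol: float = 1e-8,
             atol: float = 1e-8) -> list[dict]:
    """Steady event frequency against applied current.

    Each event (a burst counts once) contributes one count; the event type
    per current is ``spike``, ``burst`` or ``mixed`` following the marker
    classes of the published f/I figure.  An isolated compartment is modelled
    by passing ``params`` with ``gC=0``.
    """
    if compartment not in ("soma", "dendrite"):
        raise ValueError("compartment must be 'soma' or 'dendrite'")
    key = "ISapp" if compartment == "soma" else "IDapp"
    rows = []
    for I in np.asarray(I_values, dtype=float):
        p = params.replace(**{key: float(I)})
        traj = integrate(p, t_span=t_settle + t_measure, rtol=rtol, atol=atol)
        w = traj.window(t_settle)
        events = group_events(detect_spikes(w, threshold), isi_group)
        freq = len(events) / (t_measure / 1000.0)
        rows.append({"I": float(I), "freq_hz": freq,
                     "event_type": event_types(events, w)})
    return rows


# ---------------------------------------------------------------------------
# Ca--Vd phase analysis of the singlet -> doublet transition
# ---------------------------------------------------------------------------

@dataclass
class PhaseReport:
    """Per-event phases on a reference oscillation through a singlet train.

    The reference oscillation has period equal to the mean inter-peak
    interval of the early singlets' Vd peaks and is phase-shifted so its
    peaks (phase 0 deg; trough 180 deg) best match those peaks.
    """

    period: float
    t0: float  # time of a reference-oscillation peak
    vd_peak_times: np.ndarray
    ca_peak_times: np.ndarray
    vd_phases: np.ndarray  # degrees in [0, 360)
    ca_phases: np.ndarray
    phase_diff: np.ndarray  # (Ca - Vd) phase difference, degrees in [0, 360)
    peak_ikca: np.ndarray
    n_early: int  # events 0..n_early-1 are the early singlets
    last_singlet: int  # index of the last singlet before the transition


def phase_on_oscillation(times: np.ndarray, period: float,
                         t0: float) -> np.ndarray:
    """Phase (degrees, 0 = oscillation peak) of time points on a reference
    oscillation of the given period peaking at ``t0``."""
    return np.mod((np.asarray(times, dtype=float) - t0) / period, 1.0) * 360.0


def _fit_reference(peak_times: np.ndarray, period: float) -> float:
    """Peak time of the reference oscillation: circular mean alignment."""
    ph = 2 * np.pi * (peak_times / period)
    mean_angle = np.angle(np.mean(np.exp(1j * ph)))
    return (mean_angle / (2 * np.pi)) * period


def phase_analysis(traj: Trajectory, transient: float = 1000.0,
                   threshold: float = -10.0, isi_group: float | str = "auto",
                   min_singlets: int = 5) -> PhaseReport:
    """Phase relations of Vd and Ca peaks across a singlet-to-doublet
    transition, together with the peak Ca-activated K current per event.

    Requires at least ``min_singlets`` consecutive single-spike events
    immediately before the first multi-spike event.
    """
    w = traj.window(transient)
    spikes = detect_spikes(w, threshold)
    events = group_events(spikes, isi_group)
    sizes = [len(e) for e in events]
    trans = None
    for j, sz in enumerate(sizes):
        if sz >= 2 and j >= min_singlets and all(
                s == 1 for s in sizes[j - min_singlets:j]):
            trans = j
            break
    if trans is None:
        raise ValueError(
            f"no transition with >= {min_singlets} preceding singlets found")
    start = trans
    while start > 0 and sizes[start - 1] == 1:
        start -= 1
    singlets = list(range(start, trans))
    use = singlets + [trans]

    vd = w.column("Vd")
    ca = w.column("Ca")
    pr = w.params
    ikca = (pr.gKCa * w.column("c")
            * np.array([model.chi(c_, pr.variant) for c_ in ca])
            * (vd - pr.VK))

    vd_pk, ca_pk, pk_ik = [], [], []
    for j in use:
        lo = events[j][0] - 10.0
        hi = (events[j + 1][0] - 5.0 if j + 1 < len(events)
              else events[j][-1] + 50.0)
        m = (w.t >= lo) & (w.t <= hi)
        tt = w.t[m]
        vd_pk.append(tt[np.argmax(vd[m])])
        ca_pk.append(tt[np.argmax(ca[m])])
        pk_ik.append(float(ikca[m].max()))
    vd_pk, ca_pk = np.array(vd_pk), np.array(ca_pk)

    early = slice(0, len(singlets) - 1)  # all singlets but the last
    period = float(np.mean(np.diff(vd_pk[early])))
    t0 = _fit_reference(vd_pk[early], period)
    vd_phases = phase_on_oscillation(vd_pk, period, t0)
    ca_phases = phase_on_oscillation(ca_pk, period, t0)
    return PhaseReport(
        period=period, t0=t0,
        vd_peak_times=vd_pk, ca_peak_times=ca_pk,
        vd_phases=vd_phases, ca_phases=ca_phases,
        phase_diff=np.mod(ca_phases - vd_phases, 360.0),
        peak_ikca=np.array(pk_ik),
        n_early=len(singlets) - 1,
        last_singlet=len(singlets) - 1,
    )
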