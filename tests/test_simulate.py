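"""Integration, spike/burst detection, firing classification, phases."""

import numpy as np
import pytest

from pyrcell import (ModelParameters, Trajectory, classify_firing,
                     detect_spikes, group_events, integrate, phase_analysis)
from pyrcell.simulate import phase_on_oscillation


@pytest.fixture(scope="module")
def burst_traj():
    return integrate(ModelParameters(ISapp=0.75), t_span=8000.0)


class TestIntegrate:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            integrate(ModelParameters(), t_span=-5.0)
        with pytest.raises(ValueError):
            integrate(ModelParameters(), init=np.full(8, np.nan),
                      t_span=10.0)

    def test_tolerance_halving_keeps_spike_times(self):
        pars = ModelParameters(ISapp=3.0)
        a = integrate(pars, t_span=2000.0, rtol=1e-8, atol=1e-8)
        b = integrate(pars, t_span=2000.0, rtol=5e-9, atol=5e-9)
        sa = detect_spikes(a.window(500))
        sb = detect_spikes(b.window(500))
        n = min(len(sa), len(sb))
        assert n > 10
        assert np.max(np.abs(sa[:n] - sb[:n])) < 0.1

    def test_smooth_and_original_both_burst_at_075(self, burst_traj):
        fp_s = classify_firing(burst_traj)
        orig = integrate(ModelParameters(ISapp=0.75, variant="original"),
                         t_span=8000.0)
        fp_o = classify_firing(orig)
        assert fp_s.event_type == "burst"
        assert fp_o.event_type == "burst"


class TestSpikesAndEvents:
    def test_constant_trace_has_no_spikes(self):
        t = np.linspace(0, 1000, 2001)
        y = np.zeros((len(t), 8))
        y[:, 0] = -65.0
        traj = Trajectory(t, y, ModelParameters())
        assert len(detect_spikes(traj)) == 0

    def test_crossing_interpolation(self):
        t = np.array([0.0, 1.0, 2.0])
        y = np.zeros((3, 8))
        y[:, 0] = [-30.0, 10.0, -30.0]
        traj = Trajectory(t, y, ModelParameters())
        s = detect_spikes(traj, threshold=-10.0)
        assert s == pytest.approx([0.5])

    def test_grouping_fixed_and_auto(self):
        spikes = np.array([0.0, 5.0, 10.0, 500.0, 505.0, 1000.0])
        ev = group_events(spikes, 25.0)
        assert [len(e) for e in ev] == [3, 2, 1]
        # tonic train: no artificial grouping under "auto"
        tonic = np.arange(0, 400, 20.0)
        assert all(len(e) == 1 for e in group_events(tonic, "auto"))

    def test_regular_spiking_has_stable_isi(self):
        traj = integrate(ModelParameters(ISapp=3.0), t_span=5000.0)
        isi = np.diff(detect_spikes(traj.window(2000)))
        assert np.std(isi) / np.mean(isi) < 0.01


class TestClassification:
    @pytest.mark.parametrize("key,value,t_span,expected", [
        ("ISapp", -1.0, 4000.0, "hyperpolarised_rest"),
        ("ISapp", 3.0, 6000.0, "regular_spiking"),
        ("ISapp", 17.0, 5000.0, "waxing_waning"),
        ("IDapp", 0.3, 16000.0, "vlf_bursting"),
        ("IDapp", 12.0, 5000.0, "regular_spiking"),
    ])
    def test_published_regime_labels(self, key, value, t_span, expected):
        traj = integrate(ModelParameters(**{key: value}), t_span=t_span)
        assert classify_firing(traj).label == expected

    def test_classification_invariant_to_transient(self):
        traj = integrate(ModelParameters(ISapp=3.0), t_span=7000.0)
        labels = {classify_firing(traj, transient=tr).label
                  for tr in (2000.0, 3000.0, 4000.0)}
        assert labels == {"regular_spiking"}


class TestPhaseAnalysis:
    def test_synthetic_two_sinusoid_lag(self):
        # two sinusoids with an imposed lag produce a constant phase diff
        period, lag = 40.0, 10.0
        peaks_vd = np.arange(100.0, 600.0, period)
        assert np.allclose(
            np.diff(phase_on_oscillation(peaks_vd, period, peaks_vd[0])), 0)
        ph_vd = phase_on_oscillation(peaks_vd, period, peaks_vd[0])
        ph_ca = phase_on_oscillation(peaks_vd + lag, period, peaks_vd[0])
        diff = np.mod(ph_ca - ph_vd, 360.0)
        assert np.allclose(diff, 360.0 * lag / period)

    def test_requires_enough_singlets(self, burst_traj):
        with pytest.raises(ValueError):
            phase_analysis(burst_traj, min_singlets=5)

    def test_singlet_doublet_transition_at_isapp_2(self):
        traj = integrate(ModelParameters(ISapp=2.0), t_span=12000.0)
        rep = phase_analysis(traj, transient=1000.0)
        assert rep.n_early >= 4
        assert np.all((rep.vd_phases >= 0) & (rep.vd_phases < 360))
        early = slice(0, rep.n_early)
        # the last singlet is phase-advanced: smaller Ca-Vd phase
        # difference and a larger Ca-activated K current peak
        assert (rep.phase_diff[rep.last_singlet]
                < np.mean(rep.phase_diff[early]))
        assert (rep.peak_ikca[rep.last_singlet]
                > np.mean(rep.peak_ikca[early]))
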