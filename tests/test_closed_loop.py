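"""Closed-loop protocol: predictor primitives, shutter timing, causality and
offset bookkeeping on a noiseless tonically firing model."""

import math

import numpy as np
import pandas as pd
import pytest

from nirspike.closed_loop import (
    ShutterModel,
    VoltageAreaAccumulator,
    offset_analysis,
    run_closed_loop,
    update_threshold,
)
from nirspike.trace import VoltageTrace


def periodic_trace(n_cycles=6, isi_ms=250.0, dt=0.1, amp=90.0, base=-60.0,
                   growth=0.0):
    """Noiseless periodic spike train; optional per-cycle amplitude growth."""
    duration = (n_cycles + 1) * isi_ms
    t = np.arange(int(duration / dt) + 1) * dt
    v = np.full_like(t, base)
    peaks = []
    for k in range(n_cycles):
        tp = 150.0 + (k + 0.5) * isi_ms
        peaks.append(tp)
        a = amp * (1.0 + growth * k)
        v += np.clip(a * (1.0 - np.abs(t - tp) / 12.0), 0.0, None)
    return VoltageTrace(v, dt), np.array(peaks)


class TestThresholdUpdate:
    def test_tau_zero_returns_previous_peak_voltage(self):
        tr, peaks = periodic_trace()
        th = update_threshold(tr, peaks[2], 0.0)
        assert th == pytest.approx(tr.samples[tr.index_of(peaks[2])])

    def test_crossing_happens_tau_before_next_peak(self):
        """On a periodic train the updated threshold is re-crossed τ before
        every subsequent peak, within one sampling interval."""
        tr, peaks = periodic_trace()
        tau = 7.0
        th = update_threshold(tr, peaks[1], tau)
        nxt = tr.index_of(peaks[2])
        v = tr.samples
        crossing = next(i for i in range(tr.index_of(peaks[1]) + 200, nxt + 1)
                        if v[i - 1] < th <= v[i])
        assert abs((peaks[2] - crossing * tr.dt_ms) - tau) <= tr.dt_ms

    def test_threshold_tracks_drifting_amplitude(self):
        """With growing spikes the per-spike threshold follows the previous
        spike instead of a fixed preset."""
        tr, peaks = periodic_trace(growth=0.05)
        tau = 5.0
        ths = [update_threshold(tr, p, tau) for p in peaks]
        assert all(b > a for a, b in zip(ths, ths[1:]))


class TestAreaAccumulator:
    def test_stream_at_baseline_never_accumulates(self):
        acc = VoltageAreaAccumulator(0.1)
        acc.reset(-60.0)
        for _ in range(1000):
            acc.add(-60.0)
        assert acc.area == 0.0

    def test_rectangle_rule(self):
        acc = VoltageAreaAccumulator(0.1)
        acc.reset(-60.0)
        for _ in range(500):
            acc.add(-59.0)   # 1 mV above baseline
        assert acc.area == pytest.approx(500 * 0.1 * 1.0)

    def test_raw_mode_sums_unreferenced_voltage(self):
        acc = VoltageAreaAccumulator(0.1, baseline_referenced=False)
        acc.reset(-60.0)
        acc.add(-60.0)
        assert acc.area == pytest.approx(-6.0)


class TestShutter:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ShutterModel(delay_ms=-1.0)
        with pytest.raises(ValueError):
            ShutterModel(duration_ms=0.0)


@pytest.fixture(scope="module")
def sham_run():
    """Threshold-mode run with zero forcing (shutter cycles, no heating)."""
    return run_closed_loop(target_offset_ms=0.0, n_cycles=6, dT_ss=0.0,
                           warmup_ms=2000.0)


@pytest.fixture(scope="module")
def heated_run():
    return run_closed_loop(target_offset_ms=0.0, n_cycles=6, dT_ss=5.0,
                           warmup_ms=2000.0)


class TestClosedLoopRun:
    def test_shutter_timing_arithmetic(self, sham_run):
        """Onset = trigger + 8 ms; end = onset + 58 ms, for every event."""
        for ev in sham_run.events:
            assert ev.onset_ms == pytest.approx(ev.trigger_ms + 8.0)
            assert ev.end_ms == pytest.approx(ev.onset_ms + 58.0)

    def test_causality_and_one_trigger_per_cycle(self, sham_run):
        peaks = sham_run.spike_peaks
        for ev in sham_run.events:
            assert ev.onset_ms >= ev.trigger_ms
        triggers = np.array([ev.trigger_ms for ev in sham_run.events])
        for lo, hi in zip(peaks[:-1], peaks[1:]):
            assert ((triggers > lo) & (triggers <= hi)).sum() <= 1

    def test_threshold_trigger_leads_peak_by_tau(self, sham_run):
        """The crossing precedes the associated peak by the solved lead time
        within one sample of the 0.1 ms clock (noiseless periodic neuron)."""
        lead = sham_run.config["lead_ms"]
        for ev in sham_run.events:
            assert ev.spike_peak_ms - ev.trigger_ms == pytest.approx(
                lead, abs=0.2)

    def test_realized_offsets_cluster_at_target(self, sham_run):
        offs = np.array([ev.offset_ms for ev in sham_run.events])
        assert np.all(np.abs(offs - 0.0) <= 0.5)

    def test_offset_bookkeeping_round_trip(self, heated_run):
        """offset = (trigger + delay + duration) − associated peak, exactly."""
        for ev in heated_run.events:
            recomputed = (ev.trigger_ms + 8.0 + 58.0) - ev.spike_peak_ms
            assert ev.offset_ms == recomputed

    def test_sham_forcing_leaves_waveform_unchanged(self, sham_run):
        """ΔT = 0: metrics of stimulated cycles match unstimulated cycles."""
        tab = sham_run.metrics
        stim_peaks = {ev.spike_peak_ms for ev in sham_run.events}
        stim = tab[tab.peak_time_ms.isin(stim_peaks)]
        ctrl = tab[(tab.peak_time_ms < sham_run.warmup_ms)
                   & ~tab.peak_time_ms.isin(stim_peaks)]
        assert not stim.empty and not ctrl.empty
        for m in ("duration_ms", "amplitude_mV", "depol_slope", "repol_slope"):
            assert stim[m].mean() == pytest.approx(ctrl[m].mean(), rel=1e-3)

    def test_heating_shortens_stimulated_spikes(self, sham_run, heated_run):
        sham_d = sham_run.event_metrics()["duration_ms"].mean()
        hot_d = heated_run.event_metrics()["duration_ms"].mean()
        assert hot_d < sham_d

    def test_never_triggering_predictor_is_reported_not_fatal(self):
        res = run_closed_loop(predictor="area", target_offset_ms=0.0,
                              n_cycles=3, dT_ss=0.0, warmup_ms=2000.0,
                              max_duration_ms=1500.0)
        assert res.events == []

    def test_area_mode_triggers_before_depolarization_rise(self):
        """Half-cycle area threshold fires mid-cycle, ahead of the upstroke."""
        res = run_closed_loop(predictor="area", target_offset_ms=-40.0,
                              n_cycles=4, dT_ss=0.0, warmup_ms=2000.0)
        assert len(res.events) == 4
        for ev in res.events:
            assert ev.offset_ms < 0  # illumination ends before the peak


class TestOffsetAnalysis:
    def _event_metrics(self, offsets, durations):
        n = len(offsets)
        return pd.DataFrame({
            "peak_time_ms": np.arange(n) * 300.0,
            "duration_ms": durations,
            "amplitude_mV": np.full(n, 80.0),
            "depol_slope": np.full(n, 5.0),
            "repol_slope": np.full(n, -3.0),
            "offset_ms": offsets,
        })

    def test_single_bin_equals_pooled_change(self):
        em = self._event_metrics([5.0, 8.0, 12.0], [38.0, 40.0, 42.0])
        ctrl = {"duration_ms": 43.0, "amplitude_mV": 80.0,
                "depol_slope": 5.0, "repol_slope": -3.0}
        tab, argmax = offset_analysis(em, ctrl)
        row = tab[(tab.metric == "duration_ms") & (tab.n > 0)]
        assert len(row) == 1
        assert row["diff"].iloc[0] == pytest.approx(40.0 - 43.0)
        assert argmax["duration_ms"] == row["bin"].iloc[0]

    def test_normalization_endpoints(self):
        """Control maps to 0 and the sustained-laser reference to 1."""
        ctrl = {"duration_ms": 43.0, "amplitude_mV": 80.0,
                "depol_slope": 5.0, "repol_slope": -3.0}
        sus = {"duration_ms": 33.0, "amplitude_mV": 80.5,
               "depol_slope": 5.5, "repol_slope": -4.0}
        em_ctrl = self._event_metrics([5.0], [43.0])
        em_sus = self._event_metrics([5.0], [33.0])
        t0, _ = offset_analysis(em_ctrl, ctrl, sus)
        t1, _ = offset_analysis(em_sus, ctrl, sus)
        d0 = t0[(t0.metric == "duration_ms") & (t0.n > 0)]["normalized"].iloc[0]
        d1 = t1[(t1.metric == "duration_ms") & (t1.n > 0)]["normalized"].iloc[0]
        assert d0 == pytest.approx(0.0)
        assert d1 == pytest.approx(1.0)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            offset_analysis(pd.DataFrame(), {})
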