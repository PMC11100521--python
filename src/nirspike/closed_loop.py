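"""Simulated activity-dependent (closed-loop) stimulation protocol.

The real experiment predicts upcoming spikes online from the ongoing
voltage recording and opens a mechanical shutter so that a fixed-length
illumination window lands at a chosen phase of the spike. Here the
electronics are replaced by a sample-by-sample loop over the simulated
trace: the integrator and the predictor advance on the same 0.1 ms clock,
so no decision ever uses samples beyond the current time.

Two prediction modes are provided:

* voltage threshold — after every spike the trigger threshold is updated to
  the voltage the previous spike had a lead time τ before its peak,
  ``V_threshold = V[t_peak[i−1] − τ]``; the next upward crossing triggers.
* voltage area — the baseline-referenced voltage is accumulated from one
  post-spike minimum to the next and the trigger fires when the running
  area reaches a threshold predicted from the previous cycle. (The literal
  raw-sum variant, accumulating the unreferenced voltage, is retained
  behind ``baseline_referenced=False``.)

The shutter opens ``delay_ms`` (default 8 ms) after the trigger for
``duration_ms`` (default 58 ms); while open, the temperature forcing rises
with first-order kinetics toward ΔT_ss and decays symmetrically after
closing. Every stimulation carries its realized illumination offset,
defined as the signed time from the end of the illumination window to the
associated spike peak (negative when the illumination ends before the
peak), spanning the configured range −100 … +80 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as wm
from .changes import METRIC_COLUMNS
from .models import get_model
from .thermal import Q10Settings
from .trace import VoltageTrace

__all__ = [
    "ShutterModel", "StimulationEvent", "ClosedLoopResult",
    "update_threshold", "VoltageAreaAccumulator",
    "run_closed_loop", "offset_analysis",
    "OFFSET_RANGE_MS", "DEFAULT_BIN_WIDTH_MS",
]

#: probed illumination-offset range (end-of-illumination relative to peak)
OFFSET_RANGE_MS = (-100.0, 80.0)
DEFAULT_BIN_WIDTH_MS = 20.0


@dataclass
class ShutterModel:
    """Mechanical shutter: trigger-to-open delay and open duration."""

    delay_ms: float = 8.0
    duration_ms: float = 58.0

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("shutter delay must be non-negative")
        if not self.duration_ms > 0:
            raise ValueError("shutter open duration must be positive")


@dataclass
class StimulationEvent:
    """One triggered illumination and its bookkeeping."""

    trigger_ms: float
    onset_ms: float
    end_ms: float
    spike_peak_ms: float = math.nan
    offset_ms: float = math.nan   # end_ms − spike_peak_ms (signed)


def update_threshold(trace: VoltageTrace, peak_time_ms: float, tau_ms: float) -> float:
    """Prediction threshold from the previous spike: V(t_peak − τ)."""
    if tau_ms < 0:
        raise ValueError("prediction lead τ must be non-negative")
    return float(trace.samples[trace.index_of(peak_time_ms - tau_ms)])


class VoltageAreaAccumulator:
    """Running voltage-area integral reset at each spike cycle.

    Accumulates ``(V − V_ref)·Δt`` (mV·ms) where ``V_ref`` is the voltage at
    the last detected post-spike minimum; with ``baseline_referenced=False``
    the raw voltage is summed instead. ``add`` returns the updated area.
    """

    def __init__(self, sample_dt_ms: float, baseline_referenced: bool = True):
        self.dt = sample_dt_ms
        self.baseline_referenced = baseline_referenced
        self.v_ref = 0.0
        self.area = 0.0

    def reset(self, v_ref: float) -> None:
        self.v_ref = v_ref if self.baseline_referenced else 0.0
        self.area = 0.0

    def add(self, v: float) -> float:
        self.area += (v - self.v_ref) * self.dt
        return self.area


@dataclass
class ClosedLoopResult:
    trace: VoltageTrace
    events: list[StimulationEvent]
    spike_peaks: np.ndarray
    metrics: pd.DataFrame          # per-spike table (measure_trace layout)
    warmup_ms: float
    config: dict = field(default_factory=dict)

    def event_metrics(self) -> pd.DataFrame:
        """Per-event rows: realized offset joined with the associated spike's
        waveform metrics."""
        rows = []
        for ev in self.events:
            if math.isnan(ev.spike_peak_ms):
                continue
            hit = self.metrics[np.isclose(self.metrics["peak_time_ms"],
                                          ev.spike_peak_ms, atol=self.trace.dt_ms)]
            if hit.empty:
                continue
            row = hit.iloc[0].to_dict()
            row.update(trigger_ms=ev.trigger_ms, onset_ms=ev.onset_ms,
                       end_ms=ev.end_ms, offset_ms=ev.offset_ms)
            rows.append(row)
        return pd.DataFrame(rows)


def run_closed_loop(
    model: str = "cgc",
    model_params: Mapping[str, float] | None = None,
    predictor: str = "threshold",
    target_offset_ms: float = 0.0,
    n_cycles: int = 20,
    dT_ss: float = 5.0,
    tau_heat_ms: float = 700.0,
    q10: Q10Settings | None = None,
    shutter: ShutterModel | None = None,
    sample_dt_ms: float = 0.1,
    dt: float = 0.01,
    warmup_ms: float = 3000.0,
    baseline_referenced: bool = True,
    min_hysteresis_mv: float = 2.0,
    max_duration_ms: float | None = None,
) -> ClosedLoopResult:
    """Run the activity-dependent stimulation protocol on a simulated neuron.

    The model must fire tonically without stimulation. At most one
    illumination is delivered per spike cycle; the loop stops after
    ``n_cycles`` stimulations (plus a settling tail) or at the duration cap.
    A predictor that never triggers is reported through an empty event list,
    not an error.
    """
    if predictor not in ("threshold", "area"):
        raise ValueError("predictor must be 'threshold' or 'area'")
    shutter = shutter or ShutterModel()
    q10 = q10 or Q10Settings()
    mdl = get_model(model, dict(model_params) if model_params else None)
    # lead time from the desired offset, shutter delay and window length:
    # end = trigger + delay + duration and end = peak + offset
    lead_ms = shutter.delay_ms + shutter.duration_ms - target_offset_ms
    n_sub = max(1, int(round(sample_dt_ms / dt)))
    q_vec, capmask, gamma = mdl.thermal_vectors(q10)
    p_vec = mdl.param_vector()
    v_idx, g_idx = mdl.voltage_indices(), mdl.gate_indices()
    vi = mdl.state_names.index(mdl.primary_voltage)
    empty = np.empty(0)
    integ = mdl._integrator

    y = mdl.rest(dt=dt)
    det_th = mdl.detection_threshold_mv
    refractory = mdl.detection_refractory_ms

    if max_duration_ms is None:
        max_duration_ms = warmup_ms + 120_000.0
    n_max = int(round(max_duration_ms / sample_dt_ms))
    v_buf = np.empty(n_max + 1)
    v_buf[0] = y[vi]

    dT_cur = 0.0
    decay = math.exp(-sample_dt_ms / tau_heat_ms) if tau_heat_ms > 0 else 0.0
    events: list[StimulationEvent] = []
    peaks: list[float] = []
    open_until = -1.0
    pending_onset: float | None = None
    pending_event: StimulationEvent | None = None
    scheduled_trigger: float | None = None
    armed = False            # may the predictor trigger in this cycle
    v_threshold = math.nan
    # area-mode state
    acc = VoltageAreaAccumulator(sample_dt_ms, baseline_referenced)
    accumulating = False
    area_series: list[float] = []
    area_t0 = 0.0
    area_threshold = math.inf
    run_min = math.inf
    tracking_min = False
    done_at: float | None = None

    i = 0
    t = 0.0
    while i < n_max:
        t_next = (i + 1) * sample_dt_ms
        # shutter state decides the temperature target
        if pending_onset is not None and t_next >= pending_onset:
            open_until = pending_event.end_ms
            pending_onset = None
        target = dT_ss if (t_next < open_until) else 0.0
        dT_cur = target + (dT_cur - target) * decay
        # advance the model one sample with the current temperature
        status, _, _, _, _, _, y = integ(
            y, p_vec, q_vec, capmask, gamma,
            1, dT_cur, -1.0, math.inf, tau_heat_ms, empty, empty,
            dt, n_sub, n_sub, v_idx, g_idx)
        if status != 0:
            raise RuntimeError(f"closed-loop integration failed at t={t_next:.1f} ms")
        i += 1
        t = t_next
        v = y[vi]
        v_buf[i] = v

        # --- online peak detection (local maximum above threshold) ---------
        if (i >= 2 and v_buf[i - 1] > det_th
                and v_buf[i - 1] >= v_buf[i - 2] and v_buf[i - 1] > v
                and (not peaks or t - sample_dt_ms - peaks[-1] > refractory)):
            t_peak = t - sample_dt_ms
            peaks.append(t_peak)
            armed = True
            run_min = math.inf
            tracking_min = True
            if predictor == "threshold" and lead_ms > 0:
                j = i - 1 - int(round(lead_ms / sample_dt_ms))
                if j >= 0:
                    v_threshold = v_buf[j]
            elif predictor == "threshold":
                # post-peak targeting: schedule the trigger from this peak
                if t_peak > warmup_ms and len(events) < n_cycles and done_at is None:
                    scheduled_trigger = t_peak - lead_ms  # lead ≤ 0 → future
            else:
                # area mode: next cycle's threshold is the area this cycle
                # had reached a lead time before this peak
                if area_series:
                    cur = np.asarray(area_series)
                    k = int(round((t_peak - lead_ms - area_t0) / sample_dt_ms))
                    # leads reaching before the accumulation start trigger as
                    # early in the cycle as achievable
                    k = min(max(k, 0), cur.size - 1)
                    area_threshold = float(cur[k])
                accumulating = False
            if n_cycles > 0 and len(events) >= n_cycles and done_at is None:
                done_at = t + 2 * refractory + 200.0  # settle before stopping
        # --- post-spike minimum for the area reset -------------------------
        if tracking_min:
            if v < run_min:
                run_min = v
            elif v > run_min + min_hysteresis_mv:
                tracking_min = False
                acc.reset(run_min)
                area_series = []
                area_t0 = t
                accumulating = True
        if predictor == "area" and accumulating:
            a = acc.add(v)
            area_series.append(a)

        # --- trigger decision ----------------------------------------------
        can_fire = (armed and t > warmup_ms and len(events) < n_cycles
                    and t >= open_until and done_at is None)
        fired = False
        if can_fire and predictor == "threshold" and lead_ms > 0:
            if (not math.isnan(v_threshold) and v_buf[i - 1] < v_threshold <= v):
                fired = True
        elif can_fire and predictor == "area":
            if accumulating and math.isfinite(area_threshold) and acc.area >= area_threshold:
                fired = True
        if (scheduled_trigger is not None and t >= scheduled_trigger
                and len(events) < n_cycles):
            fired = True
            scheduled_trigger = None
        if fired:
            ev = StimulationEvent(
                trigger_ms=t,
                onset_ms=t + shutter.delay_ms,
                end_ms=t + shutter.delay_ms + shutter.duration_ms,
            )
            events.append(ev)
            pending_onset = ev.onset_ms
            pending_event = ev
            armed = False
        if done_at is not None and t >= done_at:
            break

    trace = VoltageTrace(v_buf[: i + 1].copy(), sample_dt_ms, 0.0)
    peak_arr = wm.detect_spikes(trace, det_th, refractory)
    # associate events with spikes: overlapping peak first, else nearest to end
    for ev in events:
        inside = peak_arr[(peak_arr >= ev.onset_ms) & (peak_arr <= ev.end_ms)]
        if inside.size:
            ev.spike_peak_ms = float(inside[0])
        elif peak_arr.size:
            ev.spike_peak_ms = float(peak_arr[np.argmin(np.abs(peak_arr - ev.end_ms))])
        if not math.isnan(ev.spike_peak_ms):
            ev.offset_ms = ev.end_ms - ev.spike_peak_ms
    table = wm.measure_trace(trace, det_th, refractory, trial_label="closed_loop")
    return ClosedLoopResult(
        trace=trace, events=events, spike_peaks=peak_arr, metrics=table,
        warmup_ms=warmup_ms,
        config=dict(model=model, predictor=predictor,
                    target_offset_ms=target_offset_ms, lead_ms=lead_ms,
                    dT_ss=dT_ss, tau_heat_ms=tau_heat_ms,
                    shutter_delay_ms=shutter.delay_ms,
                    shutter_duration_ms=shutter.duration_ms),
    )


def offset_analysis(
    event_metrics: pd.DataFrame,
    control_reference: Mapping[str, float],
    sustained_reference: Mapping[str, float] | None = None,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
    offset_range_ms: tuple[float, float] = OFFSET_RANGE_MS,
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> tuple[pd.DataFrame, dict]:
    """Per-offset-bin change summaries of the closed-loop battery.

    ``event_metrics`` is the concatenation of ``ClosedLoopResult.
    event_metrics()`` tables (one row per stimulated spike, with its
    realized ``offset_ms``). Per bin and metric the table reports the mean
    metric, its difference from the control reference and — when a
    sustained-laser reference is supplied — the min–max normalized position
    between control (0) and sustained laser (1). Returns the table and the
    argmax bin (largest absolute change) per metric.
    """
    if event_metrics.empty:
        raise ValueError("no stimulation events to analyze")
    lo, hi = offset_range_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    labels = [f"({edges[k]:g}, {edges[k+1]:g}]" for k in range(len(edges) - 1)]
    binned = pd.cut(event_metrics["offset_ms"], bins=edges, labels=labels)
    rows = []
    for lab, grp in event_metrics.groupby(binned, observed=False):
        for m in metrics:
            if grp.empty:
                rows.append({"bin": lab, "metric": m, "n": 0,
                             "mean": np.nan, "diff": np.nan, "normalized": np.nan})
                continue
            val = float(grp[m].abs().mean())
            ctrl = abs(float(control_reference[m]))
            diff = val - ctrl
            norm = np.nan
            if sustained_reference is not None:
                sus = abs(float(sustained_reference[m]))
                if sus != ctrl:
                    norm = (val - ctrl) / (sus - ctrl)
            rows.append({"bin": lab, "metric": m, "n": len(grp),
                         "mean": val, "diff": diff, "normalized": norm})
    table = pd.DataFrame(rows)
    argmax = {}
    for m in metrics:
        sub = table[(table["metric"] == m) & (table["n"] > 0)].dropna(subset=["diff"])
        if not sub.empty:
            argmax[m] = sub.loc[sub["diff"].abs().idxmax(), "bin"]
    return table, argmax
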