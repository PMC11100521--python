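"""Spike detection, segmentation, alignment and waveform metrics.

Action potentials are detected as local maxima above an absolute voltage
threshold, segmented ±100 ms around the peak, and characterized by four
scalar metrics:

* duration — time between the two half-height crossings flanking the peak;
* amplitude — max − min voltage over the segment;
* depolarization slope — (V(t+1 ms) − V(t−1 ms))/2 ms at the rising-limb
  half-height crossing;
* repolarization slope — same two-point difference at the falling-limb
  crossing (negative).

Half-height is referenced to the segment minimum, matching the min-to-max
amplitude definition; crossings are located by linear interpolation between
bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trace import VoltageTrace

__all__ = [
    "SpikeSegment", "WaveformMetrics",
    "detect_spikes", "segment", "align", "compute_metrics",
    "filter_outliers", "measure_trace",
    "SEGMENT_HALF_MS", "DEFAULT_THRESHOLD_MV", "DEFAULT_REFRACTORY_MS",
]

SEGMENT_HALF_MS = 100.0
DEFAULT_THRESHOLD_MV = 0.0   # absolute threshold; spikes overshoot 0 mV
DEFAULT_REFRACTORY_MS = 50.0  # slow Lymnaea dynamics
SLOPE_OFFSET_MS = 1.0


@dataclass
class SpikeSegment:
    """±100 ms of voltage around one spike peak."""

    samples: np.ndarray
    dt_ms: float
    peak_time_ms: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_half = int(round(SEGMENT_HALF_MS / self.dt_ms))
        if self.samples.size != 2 * n_half + 1:
            raise ValueError(
                f"segment must span ±{SEGMENT_HALF_MS} ms "
                f"({2 * n_half + 1} samples at {self.dt_ms} ms)")

    @property
    def peak_index(self) -> int:
        return self.samples.size // 2

    @property
    def times(self) -> np.ndarray:
        """Times relative to the peak (ms)."""
        return (np.arange(self.samples.size) - self.peak_index) * self.dt_ms


@dataclass
class WaveformMetrics:
    """The four scalar spike-shape metrics."""

    duration_ms: float
    amplitude_mv: float
    depol_slope: float   # mV/ms, > 0
    repol_slope: float   # mV/ms, stored signed (< 0)

    _FIELDS = ("duration_ms", "amplitude_mv", "depol_slope", "repol_slope")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS])


def detect_spikes(
    trace: VoltageTrace,
    threshold_mv: float = DEFAULT_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> np.ndarray:
    """Spike peak times (ms, absolute) above an absolute voltage threshold.

    Peaks closer than ``refractory_ms`` to a previous peak are suppressed
    (the larger wins) and peaks within 100 ms of either trace edge are
    dropped so that a full segment always fits.
    """
    distance = max(1, int(round(refractory_ms / trace.dt_ms)))
    idx, _ = find_peaks(trace.samples, height=threshold_mv, distance=distance)
    n_half = int(round(SEGMENT_HALF_MS / trace.dt_ms))
    idx = idx[(idx >= n_half) & (idx <= trace.n_samples - 1 - n_half)]
    return trace.t0_ms + idx * trace.dt_ms


def segment(trace: VoltageTrace, peak_time_ms: float) -> SpikeSegment:
    """Cut the ±100 ms window around a peak; errors if it exceeds the trace."""
    center = trace.index_of(peak_time_ms)
    n_half = int(round(SEGMENT_HALF_MS / trace.dt_ms))
    lo, hi = center - n_half, center + n_half
    if lo < 0 or hi >= trace.n_samples:
        raise ValueError(
            f"±{SEGMENT_HALF_MS} ms window around {peak_time_ms} ms exceeds the trace")
    return SpikeSegment(trace.samples[lo : hi + 1].copy(), trace.dt_ms, peak_time_ms)


def align(segments: Sequence[SpikeSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Peak-align segments and zero each at its first sample.

    Returns the aligned matrix (one row per spike) and the column-wise mean
    waveform. Segments are already peak-centered, so alignment reduces to
    subtracting each segment's first value (offset invariance).
    """
    if not segments:
        raise ValueError("no segments to align")
    mat = np.vstack([s.samples - s.samples[0] for s in segments])
    return mat, mat.mean(axis=0)


def _interp_at(v: np.ndarray, dt: float, t: float) -> float:
    """Linear interpolation of a sampled waveform at time t (segment clock)."""
    x = t / dt
    i = int(np.floor(x))
    i = min(max(i, 0), v.size - 2)
    frac = x - i
    return float(v[i] + frac * (v[i + 1] - v[i]))


def compute_metrics(seg: SpikeSegment) -> WaveformMetrics:
    """The four waveform metrics of one segmented spike."""
    v = seg.samples
    dt = seg.dt_ms
    peak = seg.peak_index
    vmin = float(v.min())
    vmax = float(v.max())
    amplitude = vmax - vmin
    if amplitude <= 0:
        raise ValueError("flat segment has no spike")
    half = vmin + amplitude / 2.0

    # last upward crossing of the half level before the peak
    t_rise = None
    for i in range(peak - 1, -1, -1):
        if v[i] < half <= v[i + 1]:
            frac = (half - v[i]) / (v[i + 1] - v[i])
            t_rise = (i + frac) * dt
            break
    if t_rise is None:
        raise ValueError("no half-height crossing on the depolarization limb")

    # first downward crossing after the peak
    t_fall = None
    for i in range(peak, v.size - 1):
        if v[i] >= half > v[i + 1]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            t_fall = (i + frac) * dt
            break
    if t_fall is None:
        raise ValueError("no half-height crossing on the repolarization limb")

    def two_point_slope(t_c: float) -> float:
        hi = _interp_at(v, dt, t_c + SLOPE_OFFSET_MS)
        lo = _interp_at(v, dt, t_c - SLOPE_OFFSET_MS)
        return (hi - lo) / (2.0 * SLOPE_OFFSET_MS)

    return WaveformMetrics(
        duration_ms=t_fall - t_rise,
        amplitude_mv=amplitude,
        depol_slope=two_point_slope(t_rise),
        repol_slope=two_point_slope(t_fall),
    )


def filter_outliers(
    metrics_list: Iterable[WaveformMetrics],
    zscore_cutoff: float = -0.1,
) -> tuple[list[WaveformMetrics], int]:
    """Drop non-stereotyped spikes by z-score of the normalized duration.

    Entries whose duration z-score falls below ``zscore_cutoff`` are removed
    (default −0.1; note that such a cutoff prunes a sizeable fraction of any
    symmetric distribution, hence it is configurable). Returns the retained
    list and the removed count.
    """
    mlist = list(metrics_list)
    if len(mlist) < 2:
        return mlist, 0
    d = np.array([m.duration_ms for m in mlist])
    norm = d / d.mean() if d.mean() != 0 else d
    sd = norm.std()
    if sd == 0:
        return mlist, 0
    z = (norm - norm.mean()) / sd
    kept = [m for m, zi in zip(mlist, z) if zi >= zscore_cutoff]
    return kept, len(mlist) - len(kept)


def measure_trace(
    trace: VoltageTrace,
    threshold_mv: float = DEFAULT_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    trial_label: str = "",
) -> pd.DataFrame:
    """Detect, segment and measure every spike of a trace.

    Returns one row per spike with columns peak_time_ms, duration_ms,
    amplitude_mV, depol_slope, repol_slope and trial_label — the per-spike
    metric table consumed by the change statistics.
    """
    rows = []
    for t_peak in detect_spikes(trace, threshold_mv, refractory_ms):
        m = compute_metrics(segment(trace, t_peak))
        rows.append({
            "peak_time_ms": t_peak,
            "duration_ms": m.duration_ms,
            "amplitude_mV": m.amplitude_mv,
            "depol_slope": m.depol_slope,
            "repol_slope": m.repol_slope,
            "trial_label": trial_label,
        })
    return pd.DataFrame(
        rows,
        columns=["peak_time_ms", "duration_ms", "amplitude_mV",
                 "depol_slope", "repol_slope", "trial_label"],
    )
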