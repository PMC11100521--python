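"""Shared fixtures: session-scoped simulations reused across test modules."""

import numpy as np
import pytest

from nirspike import metrics as wm
from nirspike.models import get_model
from nirspike.trace import VoltageTrace


def simulate(name, duration_ms, dt=0.01, **kwargs):
    """Rest-settled simulation of a model at nominal parameters."""
    m = get_model(name, kwargs.pop("params", None))
    y0 = m.rest(dt=dt)
    return m, m.integrate(duration_ms, dt=dt, y0=y0, **kwargs)


@pytest.fixture(scope="session")
def hh_run():
    return simulate("hh", 4000)


@pytest.fixture(scope="session")
def cgc_run():
    return simulate("cgc", 8000)


@pytest.fixture(scope="session")
def n3t_run():
    return simulate("n3t", 4000)


@pytest.fixture(scope="session")
def model_runs(hh_run, cgc_run, n3t_run):
    return {"hh": hh_run, "cgc": cgc_run, "n3t": n3t_run}


def spike_peaks(model, result, t_min_ms=2000.0):
    tr = result.trace()
    peaks = wm.detect_spikes(tr, model.detection_threshold_mv,
                             model.detection_refractory_ms)
    return tr, peaks[peaks >= t_min_ms]


# --- analytic spike fixtures --------------------------------------------------

def triangle_segment(dt_ms=0.1, rise_ms=10.0, amplitude_mv=100.0):
    """Symmetric triangular spike on a flat zero baseline, peak-centered."""
    n_half = int(round(wm.SEGMENT_HALF_MS / dt_ms))
    t = (np.arange(2 * n_half + 1) - n_half) * dt_ms
    v = np.clip(amplitude_mv * (1.0 - np.abs(t) / rise_ms), 0.0, None)
    return wm.SpikeSegment(v, dt_ms, peak_time_ms=0.0)


def gaussian_segment(dt_ms=0.1, sigma_ms=5.0, amplitude_mv=80.0):
    n_half = int(round(wm.SEGMENT_HALF_MS / dt_ms))
    t = (np.arange(2 * n_half + 1) - n_half) * dt_ms
    v = amplitude_mv * np.exp(-(t ** 2) / (2 * sigma_ms ** 2))
    return wm.SpikeSegment(v, dt_ms, peak_time_ms=0.0)


def spike_train_trace(n_spikes=7, isi_ms=300.0, dt_ms=0.1, width_ms=8.0,
                      amplitude_mv=90.0, baseline_mv=-60.0):
    """Deterministic train of identical triangular spikes."""
    duration = (n_spikes + 1) * isi_ms + 200.0
    n = int(round(duration / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    v = np.full(n, baseline_mv)
    peaks = []
    for k in range(n_spikes):
        tp = 150.0 + (k + 0.5) * isi_ms
        peaks.append(tp)
        v += np.clip(amplitude_mv * (1.0 - np.abs(t - tp) / (width_ms / 2)), 0.0, None)
    return VoltageTrace(v, dt_ms, 0.0), np.array(peaks)
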