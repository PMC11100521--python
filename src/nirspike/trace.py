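"""Uniformly sampled membrane-potential traces.

The canonical recording format in this package mirrors the acquisition used
for *Lymnaea stagnalis* intracellular data: membrane voltage in mV sampled
at 10 kHz (0.1 ms interval). Model output is down-sampled to the same grid
so the analysis code never distinguishes simulated from recorded material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoltageTrace"]


@dataclass
class VoltageTrace:
    """A uniformly sampled voltage recording.

    Parameters
    ----------
    samples :
        Membrane potential in mV.
    dt_ms :
        Sampling interval in ms (default 0.1 ms, i.e. 10 kHz).
    t0_ms :
        Absolute time of the first sample in ms.
    """

    samples: np.ndarray
    dt_ms: float = 0.1
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not self.dt_ms > 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) * self.dt_ms

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in ms."""
        return self.t0_ms + self.dt_ms * np.arange(self.n_samples)

    def index_of(self, t_ms: float) -> int:
        """Nearest sample index for an absolute time."""
        idx = int(round((t_ms - self.t0_ms) / self.dt_ms))
        if idx < 0 or idx >= self.n_samples:
            raise IndexError(f"time {t_ms} ms outside trace")
        return idx

    def slice(self, t_start_ms: float, t_stop_ms: float) -> "VoltageTrace":
        i0 = self.index_of(t_start_ms)
        i1 = self.index_of(t_stop_ms)
        return VoltageTrace(self.samples[i0 : i1 + 1], self.dt_ms, self.t0_ms + i0 * self.dt_ms)

    # --- plain-text round trip -------------------------------------------------
    def to_text(self, path) -> None:
        """Write as two-column delimited text (time_ms, voltage_mV)."""
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            fmt="%.6f",
            header="time_ms\tvoltage_mV",
            delimiter="\t",
        )

    @classmethod
    def from_text(cls, path) -> "VoltageTrace":
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
            raise ValueError("expected two-column (time_ms, voltage_mV) text")
        t, v = data[:, 0], data[:, 1]
        dts = np.diff(t)
        dt = float(np.median(dts))
        if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("trace is not uniformly sampled")
        return cls(v, dt, float(t[0]))
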