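"""Biophysical-candidate parameter sweeps and temperature studies.

Reproduces the model-side analysis: one biophysical candidate (capacitance
or one maximal conductance) is swept across a grid while all else stays
nominal; each grid point is simulated long enough to collect a stereotyped
spike population, the four waveform metrics are averaged, and the sweep is
summarized by the normalized model change |min − max|/|max| per metric,
optionally mapped onto an experimental MEC reference via the gradient
score. Temperature sweeps scale every enabled parameter with the Q10 law
instead of varying a single conductance, and the channel-dependency study
toggles the temperature dependence of one channel (with its gates) at a
time, in "only-one" or "all-but-one" mode.

Grid points that fail to spike tonically (fewer than ``min_spikes`` after
the transient) are marked non-viable and excluded from the change
quantification; sweeps are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as wm
from .changes import METRIC_COLUMNS, MECReference, gradient_value, model_change
from .models import ConductanceModel, get_model
from .thermal import Q10Settings, TemperatureProtocol

__all__ = [
    "SweepSpec", "SweepResult",
    "run_sweep", "temperature_sweep", "channel_dependency_study",
    "build_similarity_table", "match_temperature",
    "default_capacitance_grid", "default_conductance_grid", "default_dT_grid",
]

#: sweep target name for temperature sweeps
TEMPERATURE_PARAM = "dT"


def default_capacitance_grid(nominal: float) -> np.ndarray:
    """0.5–1.5× nominal in 11 steps (spans the 0.5 µF/cm² extreme)."""
    return nominal * np.linspace(0.5, 1.5, 11)


def default_conductance_grid(nominal: float) -> np.ndarray:
    """0.25–2× nominal in 15 steps."""
    return nominal * np.linspace(0.25, 2.0, 15)


def default_dT_grid() -> np.ndarray:
    """ΔT = 0–10 °C in 1 °C steps."""
    return np.arange(0.0, 11.0, 1.0)


@dataclass
class SweepSpec:
    """One-candidate sweep configuration."""

    model: str
    parameter: str                      # model parameter name, or "dT"
    grid: Sequence[float]
    model_params: Mapping[str, float] = field(default_factory=dict)
    q10: Q10Settings | None = None      # temperature sweeps only
    duration_ms: float = 10_000.0
    transient_ms: float = 2_000.0
    min_spikes: int = 5
    dt: float = 0.01
    record_dt: float = 0.1

    def __post_init__(self) -> None:
        self.grid = np.asarray(list(self.grid), dtype=float)
        if self.grid.size < 2:
            raise ValueError("sweep grid needs at least 2 values")
        if self.transient_ms >= self.duration_ms:
            raise ValueError("transient exceeds the simulation duration")


@dataclass
class SweepResult:
    """Per-grid-point metric means plus the aggregated normalized changes."""

    spec: SweepSpec
    table: pd.DataFrame       # index = grid value; metric means, viable, n_spikes
    changes: Mapping[str, float]   # metric -> |min-max|/|max| over viable points

    def viable(self) -> pd.DataFrame:
        return self.table[self.table["viable"]]

    def gradient_scores(self, mec_ref: MECReference) -> dict:
        return {m: gradient_value(self.changes[m], mec_ref.mu[m], mec_ref.sigma[m])
                for m in self.changes}

    def relative_change_curves(self) -> pd.DataFrame:
        """Signed relative change of each metric vs the first grid point.

        For temperature sweeps whose grid starts at ΔT = 0 this gives the
        metric-vs-ΔT curves (change relative to the unheated simulation).
        """
        tab = self.viable()[list(METRIC_COLUMNS)].abs()
        base = tab.iloc[0]
        return (tab - base) / base.abs()


def _simulate_point(model: ConductanceModel, spec: SweepSpec,
                    overrides: Mapping[str, float] | None,
                    protocol: TemperatureProtocol | None,
                    q10: Q10Settings | None) -> dict:
    if overrides:
        point_model = get_model(spec.model, {**dict(model.params), **overrides})
    else:
        point_model = model
    y0 = point_model.rest(dt=spec.dt)
    res = point_model.integrate(spec.duration_ms, dt=spec.dt,
                                record_dt=spec.record_dt,
                                protocol=protocol, q10=q10, y0=y0)
    tr = res.trace()
    peaks = wm.detect_spikes(tr, model.detection_threshold_mv,
                             model.detection_refractory_ms)
    peaks = peaks[peaks >= spec.transient_ms]
    out = {"n_spikes": len(peaks), "viable": len(peaks) >= spec.min_spikes}
    if out["viable"]:
        mlist = [wm.compute_metrics(wm.segment(tr, t)) for t in peaks]
        out["duration_ms"] = float(np.mean([m.duration_ms for m in mlist]))
        out["amplitude_mV"] = float(np.mean([m.amplitude_mv for m in mlist]))
        out["depol_slope"] = float(np.mean([m.depol_slope for m in mlist]))
        out["repol_slope"] = float(np.mean([m.repol_slope for m in mlist]))
    else:
        for c in METRIC_COLUMNS:
            out[c] = np.nan
    return out


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Sweep one biophysical candidate (or ΔT) and quantify the change."""
    model = get_model(spec.model, dict(spec.model_params) or None)
    rows = []
    for value in spec.grid:
        if spec.parameter == TEMPERATURE_PARAM:
            q10 = spec.q10 or Q10Settings()
            protocol = (TemperatureProtocol(mode="constant", T0=q10.T0,
                                            dT_ss=float(value), t_on_ms=0.0)
                        if value > 0 else None)
            row = _simulate_point(model, spec, None, protocol,
                                  q10 if value > 0 else None)
        else:
            if spec.parameter not in model.param_names:
                raise KeyError(
                    f"{spec.parameter!r} is not a parameter of {spec.model}")
            row = _simulate_point(model, spec, {spec.parameter: float(value)},
                                  None, None)
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(spec.grid, name=spec.parameter))
    viable = table[table["viable"]]
    if viable.empty:
        raise RuntimeError(
            f"no viable (tonically spiking) grid point in sweep of {spec.parameter}")
    changes = {m: model_change(viable[m].to_numpy()) for m in METRIC_COLUMNS}
    return SweepResult(spec=spec, table=table, changes=changes)


def temperature_sweep(
    dT_grid: Sequence[float] | None = None,
    q10: Q10Settings | None = None,
    model: str = "cgc",
    model_params: Mapping[str, float] | None = None,
    **spec_kwargs,
) -> SweepResult:
    """Full-temperature sweep: every enabled parameter Q10-scaled at each ΔT."""
    spec = SweepSpec(
        model=model,
        parameter=TEMPERATURE_PARAM,
        grid=default_dT_grid() if dT_grid is None else dT_grid,
        model_params=model_params or {},
        q10=q10 or Q10Settings(),
        **spec_kwargs,
    )
    return run_sweep(spec)


def channel_dependency_study(
    mode: str,
    dT: float,
    q10: Q10Settings | None = None,
    model: str = "cgc",
    include_capacitance: bool = True,
    model_params: Mapping[str, float] | None = None,
    **spec_kwargs,
) -> dict[str, SweepResult]:
    """Per-channel temperature-dependence toggling study.

    ``mode="only-one"``: each channel (with its gates) is the only
    temperature-dependent element; ``mode="all-but-one"``: each channel is
    the only temperature-independent element. Returns one ΔT ∈ {0, dT}
    sweep per channel (optionally plus ``"capacitance"``).
    """
    if mode not in ("only-one", "all-but-one"):
        raise ValueError("mode must be 'only-one' or 'all-but-one'")
    mdl = get_model(model)
    base = q10 or Q10Settings()
    # explicit flag universe for this model
    full_c = {c: True for c in mdl.channels}
    full_g = {g: True for gates in mdl.channel_gates.values() for g in gates}
    results: dict[str, SweepResult] = {}
    entries = [(c, (c,), mdl.channel_gates[c], False) for c in mdl.channels]
    if include_capacitance:
        entries.append(("capacitance", (), (), True))
    for name, chans, gates, cap in entries:
        if mode == "only-one":
            settings = replace(
                base,
                conductance_enabled={**{c: False for c in full_c},
                                     **{c: True for c in chans}},
                gate_enabled={**{g: False for g in full_g},
                              **{g: True for g in gates}},
                capacitance_enabled=cap,
            )
        else:
            settings = replace(
                base,
                conductance_enabled={**full_c, **{c: False for c in chans}},
                gate_enabled={**full_g, **{g: False for g in gates}},
                capacitance_enabled=not cap,
            )
        results[name] = temperature_sweep([0.0, dT], q10=settings, model=model,
                                          model_params=model_params, **spec_kwargs)
    return results


def build_similarity_table(
    results: Mapping[str, SweepResult],
    mec_ref: MECReference,
) -> pd.DataFrame:
    """Candidate × metric table of model changes with gradient scores.

    One row per swept candidate; per metric three columns: the normalized
    change (fraction), its gradient score against (μMEC ± 2σMEC), and the
    in-range flag.
    """
    rows = {}
    for cand, res in results.items():
        row = {}
        for m in METRIC_COLUMNS:
            gs = gradient_value(res.changes[m], mec_ref.mu[m], mec_ref.sigma[m])
            row[(m, "change")] = gs.value
            row[(m, "score")] = gs.score
            row[(m, "in_range")] = gs.in_range
        rows[cand] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["metric", "field"])
    return df


def match_temperature(
    change_vector: Mapping[str, float],
    sweep: SweepResult,
    resolution: float = 0.05,
) -> float:
    """Estimate the ΔT whose sweep change profile best matches a measurement.

    ``change_vector`` holds signed relative changes (laser vs control, on
    metric magnitudes) for the four metrics; the sweep must be a temperature
    sweep whose grid starts at ΔT = 0. Curves are linearly interpolated on a
    fine ΔT grid and the least-squares ΔT is returned.
    """
    if sweep.spec.parameter != TEMPERATURE_PARAM:
        raise ValueError("match_temperature needs a temperature sweep")
    curves = sweep.relative_change_curves()
    grid = curves.index.to_numpy(dtype=float)
    if grid[0] != 0.0:
        raise ValueError("temperature sweep grid must start at ΔT = 0")
    fine = np.arange(grid[0], grid[-1] + resolution / 2, resolution)
    cost = np.zeros_like(fine)
    for m in METRIC_COLUMNS:
        target = float(change_vector[m])
        interp = np.interp(fine, grid, curves[m].to_numpy(dtype=float))
        cost += (interp - target) ** 2
    return float(fine[np.argmin(cost)])
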