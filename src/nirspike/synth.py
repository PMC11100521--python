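"""Synthetic intracellular-recording generator.

Replaces the wet-lab side of the study: tonic-spiking membrane-potential
recordings at 10 kHz from two neuron morphologies — a symmetrical-spike
cell (time-rescaled Hodgkin–Huxley, ≈15 ms half-width) and a
shoulder-spike cell (CGC model, ≈40 ms half-width) — organized in
control / laser / recovery trial triplets where the "laser" trial is the
same model under a temperature forcing of known ΔT.

Realism knobs, all seeded and recorded in a regeneration manifest:

* inter-spike-interval variability from an Ornstein–Uhlenbeck fluctuation
  of the injected current (held piecewise-constant over 50 ms update
  blocks), so waveform shape and timing covary as in a real neuron;
* additive Gaussian recording noise (default σ = 0.5 mV);
* slow sinusoidal baseline drift (default ≤ 2 mV peak-to-peak per trial);
* across-"individual" heterogeneity through multiplicative jitter of the
  maximal conductances.

Ground-truth spike times are taken from the clean model output before
noise is added. The same seed always reproduces the same traces.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np

from . import metrics as wm
from .changes import METRIC_COLUMNS, TrialTriplet
from .models import get_model
from .thermal import Q10Settings, TemperatureProtocol
from .trace import VoltageTrace

__all__ = [
    "NEURON_TYPES", "SyntheticExperimentSpec", "SyntheticTrace",
    "TripletTraces", "SyntheticBattery",
    "generate_trace", "generate_triplet", "generate_battery",
    "measure_triplet", "change_vector",
]

#: base model configuration per emulated neuron morphology
NEURON_TYPES: dict[str, dict] = {
    "shoulder": dict(
        model="cgc",
        params={},
        iinj_param="Iinj",
        ou_sigma=0.004,        # µA/cm²; the CGC pacemaker is very sensitive
        threshold_mv=0.0,
        refractory_ms=50.0,
    ),
    "symmetrical": dict(
        model="hh",
        # φ = 0.1 with Cm ×10 rescales time tenfold: ~15 ms spikes at
        # molluscan pace while preserving the classic dynamics
        params={"phi_m": 0.1, "phi_h": 0.1, "phi_n": 0.1,
                "Cm": 10.0, "Iinj": 10.0},
        iinj_param="Iinj",
        ou_sigma=0.3,
        threshold_mv=0.0,
        refractory_ms=50.0,
    ),
}

_OU_BLOCK_MS = 50.0


@dataclass
class SyntheticExperimentSpec:
    """Fully resolved recipe for one synthetic trial (seed-deterministic)."""

    neuron_type: str = "shoulder"
    duration_s: float = 60.0
    noise_sd_mv: float = 0.5
    drift_amp_mv: float = 1.0       # sinusoidal amplitude (≤2 mV over a trial)
    drift_period_s: float = 90.0
    ou_sigma: float | None = None   # None → per-type default
    ou_tau_ms: float = 500.0
    dT_ss: float = 0.0
    laser_mode: str = "constant"    # "constant" | "kinetic"
    tau_heat_ms: float = 700.0
    q10: Q10Settings = field(default_factory=Q10Settings)
    model_params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    settle_ms: float = 2000.0
    sample_dt_ms: float = 0.1
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.neuron_type not in NEURON_TYPES:
            raise ValueError(f"neuron_type must be one of {sorted(NEURON_TYPES)}")
        if self.dT_ss < 0:
            raise ValueError("ΔT_ss must be non-negative")

    @property
    def type_config(self) -> dict:
        return NEURON_TYPES[self.neuron_type]

    def resolved_ou_sigma(self) -> float:
        return (self.type_config["ou_sigma"] if self.ou_sigma is None
                else self.ou_sigma)


@dataclass
class SyntheticTrace:
    """A generated recording with its clean counterpart and ground truth."""

    trace: VoltageTrace            # noisy, 10 kHz
    clean: VoltageTrace
    truth_peaks_ms: np.ndarray
    spec: SyntheticExperimentSpec


def _protocol(spec: SyntheticExperimentSpec) -> TemperatureProtocol | None:
    if spec.dT_ss == 0:
        return None
    mode = "constant" if spec.laser_mode == "constant" else "kinetic"
    return TemperatureProtocol(mode=mode, T0=spec.q10.T0, dT_ss=spec.dT_ss,
                               t_on_ms=0.0, tau_heat_ms=spec.tau_heat_ms)


def generate_trace(spec: SyntheticExperimentSpec) -> SyntheticTrace:
    """Simulate one trial: model + OU drive, then noise and drift on top."""
    cfg = spec.type_config
    params = {**cfg["params"], **dict(spec.model_params)}
    model = get_model(cfg["model"], params)
    ss = np.random.SeedSequence(spec.seed)
    rng_ou, rng_noise, rng_drift = (np.random.default_rng(s) for s in ss.spawn(3))

    protocol = _protocol(spec)
    base_iinj = model.params[cfg["iinj_param"]]
    sigma = spec.resolved_ou_sigma()
    a = np.exp(-_OU_BLOCK_MS / spec.ou_tau_ms)
    b = sigma * np.sqrt(1.0 - a * a)

    y = model.rest(dt=spec.dt)
    duration_ms = spec.duration_s * 1000.0
    n_chunks = int(round(duration_ms / _OU_BLOCK_MS))
    pieces = [np.array([y[model.state_names.index(model.primary_voltage)]])]
    x = 0.0
    t = 0.0
    for _ in range(n_chunks):
        x = a * x + b * rng_ou.standard_normal()
        dT = float(protocol.delta_T(t + _OU_BLOCK_MS / 2)) if protocol else 0.0
        chunk_prot = (TemperatureProtocol(mode="constant", T0=spec.q10.T0,
                                          dT_ss=dT, t_on_ms=0.0)
                      if dT > 0 else None)
        res = model.integrate(
            _OU_BLOCK_MS, dt=spec.dt, record_dt=spec.sample_dt_ms,
            protocol=chunk_prot, q10=spec.q10 if dT > 0 else None, y0=y,
            param_overrides={cfg["iinj_param"]: base_iinj + x},
        )
        y = res.final_state
        pieces.append(res.voltage()[1:])   # drop duplicated boundary sample
        t += _OU_BLOCK_MS
    v_clean = np.concatenate(pieces)
    clean = VoltageTrace(v_clean, spec.sample_dt_ms, 0.0)
    truth = wm.detect_spikes(clean, cfg["threshold_mv"], cfg["refractory_ms"])

    times = clean.times
    phase = rng_drift.uniform(0, 2 * np.pi)
    drift = spec.drift_amp_mv * np.sin(
        2 * np.pi * times / (spec.drift_period_s * 1000.0) + phase)
    noise = rng_noise.normal(0.0, spec.noise_sd_mv, v_clean.size)
    noisy = VoltageTrace(v_clean + drift + noise, spec.sample_dt_ms, 0.0)
    return SyntheticTrace(trace=noisy, clean=clean, truth_peaks_ms=truth, spec=spec)


@dataclass
class TripletTraces:
    """Control / laser / recovery traces of one synthetic experiment."""

    control: SyntheticTrace
    laser: SyntheticTrace
    recovery: SyntheticTrace

    def manifest(self) -> dict:
        out = {}
        for trial in ("control", "laser", "recovery"):
            spec = getattr(self, trial).spec
            d = asdict(spec)
            d["q10"] = asdict(spec.q10)
            out[trial] = d
        return out


def generate_triplet(spec: SyntheticExperimentSpec) -> TripletTraces:
    """Control and recovery at ΔT = 0, laser at the spec's ΔT_ss.

    The three trials share the model parameters and differ only in their
    seeded noise substreams (and the thermal forcing of the laser trial).
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    control = generate_trace(replace(spec, dT_ss=0.0, seed=seeds[0]))
    laser = generate_trace(replace(spec, seed=seeds[1]))
    recovery = generate_trace(replace(spec, dT_ss=0.0, seed=seeds[2]))
    return TripletTraces(control=control, laser=laser, recovery=recovery)


@dataclass
class SyntheticBattery:
    """N synthetic experiments with across-individual heterogeneity."""

    experiments: list[TripletTraces]
    manifest: list[dict]

    def __len__(self) -> int:
        return len(self.experiments)


def generate_battery(
    n_experiments: int = 23,
    heterogeneity: float = 0.1,
    seed: int = 0,
    dT_ss: float = 5.0,
    shoulder_fraction: float = 0.5,
    base_spec: SyntheticExperimentSpec | None = None,
) -> SyntheticBattery:
    """Generate a battery of triplets with jittered conductances.

    ``heterogeneity`` is the coefficient of variation of a mean-preserving
    log-normal factor applied per experiment to each maximal conductance
    (the exquisitely sensitive CGC pacemaker conductance gNaP is jittered at
    a quarter of that CV to keep every individual tonically spiking). The
    per-experiment manifest records neuron type, resolved parameters, ΔT
    and seeds, so any experiment can be regenerated bit-exactly.
    """
    base = base_spec or SyntheticExperimentSpec()
    ss = np.random.SeedSequence(seed)
    n_shoulder = int(round(n_experiments * shoulder_fraction))
    experiments, manifest = [], []
    for i, child in enumerate(ss.spawn(n_experiments)):
        rng = np.random.default_rng(child)
        ntype = "shoulder" if i < n_shoulder else "symmetrical"
        cfg = NEURON_TYPES[ntype]
        model = get_model(cfg["model"], cfg["params"] or None)
        jitter = {}
        for pname in model.conductance_channel:
            cv = heterogeneity / 4 if pname == "gNaP" else heterogeneity
            if cv > 0:
                factor = float(np.exp(rng.normal(-0.5 * cv ** 2, cv)))
                jitter[pname] = model.params[pname] * factor
        exp_seed = int(child.generate_state(1)[0] % (2**31))
        spec = replace(base, neuron_type=ntype, dT_ss=dT_ss,
                       model_params={**dict(base.model_params), **jitter},
                       seed=exp_seed)
        trip = generate_triplet(spec)
        experiments.append(trip)
        manifest.append({"index": i, "neuron_type": ntype, "dT_ss": dT_ss,
                         "seed": exp_seed, "model_params": dict(spec.model_params)})
    return SyntheticBattery(experiments=experiments, manifest=manifest)


def measure_triplet(trip: TripletTraces,
                    zscore_cutoff: float | None = None) -> TrialTriplet:
    """Run detection + waveform metrics on a triplet's noisy traces.

    Produces the ``TrialTriplet`` consumed by the change statistics, with
    per-trial durations and spike times. ``zscore_cutoff`` optionally
    applies the stereotypy filter to each trial's duration distribution.
    """
    cfg = trip.control.spec.type_config
    tables, durations, times = {}, {}, {}
    for trial in ("control", "laser", "recovery"):
        st: SyntheticTrace = getattr(trip, trial)
        tab = wm.measure_trace(st.trace, cfg["threshold_mv"],
                               cfg["refractory_ms"], trial_label=trial)
        if zscore_cutoff is not None and len(tab) >= 2:
            d = tab["duration_ms"].to_numpy()
            norm = d / d.mean()
            sd = norm.std()
            if sd > 0:
                tab = tab[(norm - norm.mean()) / sd >= zscore_cutoff]
        tables[trial] = tab.reset_index(drop=True)
        durations[trial] = st.spec.duration_s
        times[trial] = tab["peak_time_ms"].to_numpy()
    return TrialTriplet(tables["control"], tables["laser"], tables["recovery"],
                        duration_s=durations, spike_times=times)


def change_vector(triplet: TrialTriplet) -> dict[str, float]:
    """Signed relative laser-vs-control change of the four metric magnitudes."""
    ctrl = triplet.metric_means("control")
    las = triplet.metric_means("laser")
    return {m: float((las[m] - ctrl[m]) / abs(ctrl[m])) for m in METRIC_COLUMNS}
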