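# nirspike

Simulation and analysis of how continuous-wave near-infrared (CW-NIR) laser
illumination modulates the spike dynamics of single tonically firing
neurons, built around the photothermal working hypothesis: illumination is
represented as a temperature forcing ΔT(t) acting on conductance-based
membrane models through the Q10 law,

    g_i(T) = ḡ_i · Q10^((T−T0)/10)        (maximal conductances)
    φ_i(T) = φ̄_i · Q10^((T−T0)/10)        (gate kinetics)
    C(T)   = c0 · (1 + γ·(T−T0)),  γ = 0.05 /°C

with Q10 = 3 by default for every channel and gate, each individually
overridable. The package is aimed at computational neuroscientists and
neurophotonics researchers who want to reason about which biophysical
candidates (capacitance, specific ionic channels, global temperature
dependence) can explain observed waveform changes, and to prototype
activity-dependent (closed-loop) stimulation protocols without hardware.

It provides:

* three deterministic conductance-based models — classic Hodgkin–Huxley, a
  six-current *Lymnaea stagnalis* cerebral-giant-cell (CGC) model with a
  calcium-dependent shoulder-shaped spike, and a two-compartment slow/fast
  (N3t-type) model — integrated with fixed-step RK4 (dt = 0.01 ms) and
  recorded at 10 kHz;
* spike detection, ±100 ms segmentation, alignment and the four waveform
  metrics: half-width duration, min-to-max amplitude, and the
  depolarization/repolarization slopes measured ±1 ms around the
  half-height crossings;
* change statistics: normalized laser-vs-control change, the
  across-experiment MEC reference (μ ± 2σ similarity range with affine
  gradient scoring), paired t-tests with a Bonferroni-corrected
  high-significance gate (p < 0.01/4), and firing-rate/ISI analysis with
  the ±10% excitation/inhibition classification;
* biophysical-candidate parameter sweeps (capacitance, each conductance,
  ΔT 0–10 °C) and per-channel temperature-dependence toggling;
* a sample-accurate closed-loop stimulation simulator (online spike
  prediction by adaptive voltage threshold or voltage area, an 8 ms-delay /
  58 ms-window shutter, first-order heating) with illumination-offset
  analysis;
* a seeded synthetic-recording generator (two spike morphologies, OU-driven
  ISI variability, noise, drift, control/laser/recovery triplets) standing
  in for intracellular recordings.

## Worked example

Heat the shoulder-spike CGC model by 5 °C and quantify the waveform change:

```python
import numpy as np
from nirspike.sweeps import temperature_sweep

sweep = temperature_sweep(dT_grid=np.arange(0.0, 6.0, 1.0))
print(sweep.viable()[["duration_ms", "amplitude_mV", "repol_slope"]].round(2))
print((100 * sweep.relative_change_curves().loc[5.0]).round(1))
```

prints

```
     duration_ms  amplitude_mV  repol_slope
dT
0.0        43.22        111.92        -0.54
1.0        41.64        112.62        -0.64
2.0        39.12        112.81        -0.74
3.0        36.26        112.83        -0.85
4.0        33.33        112.75        -0.98
5.0        30.47        112.59        -1.11
duration_ms     -29.5
amplitude_mV      0.6
depol_slope       2.1
repol_slope     104.8
```

Reading the output: as ΔT rises 0 → 5 °C the spike narrows monotonically
(duration −30%), the repolarization slope steepens by far the most (+105%),
the depolarization slope changes mildly and the amplitude barely moves
(+1%) — the characteristic fingerprint of a global temperature effect on
channel kinetics, as opposed to single-candidate modulation (sweeping one
conductance or the capacitance alone cannot produce this combination).

The closed-loop simulator probes the same effect at chosen spike phases:

```python
from nirspike.closed_loop import run_closed_loop

res = run_closed_loop(target_offset_ms=0.0, n_cycles=5, dT_ss=5.0)
ev = res.events[0]
print(f"trigger {ev.trigger_ms:.1f} ms -> shutter open "
      f"{ev.onset_ms:.1f}-{ev.end_ms:.1f} ms, spike peak {ev.spike_peak_ms:.1f} ms, "
      f"offset {ev.offset_ms:+.1f} ms")
```

```
trigger 3188.0 ms -> shutter open 3196.0-3254.0 ms, spike peak 3253.1 ms, offset +0.9 ms
```

i.e. the predictor fired 66 ms ahead so that the 58 ms illumination window
(which opens 8 ms after the trigger) ends at the spike peak; the realized
offset (+0.9 ms) is slightly late because the heating itself advances the
peak — which is why realized offsets are always measured, never assumed.

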