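# Methods

`nirspike` simulates and analyzes how continuous-wave near-infrared (CW-NIR)
laser illumination modulates the spike dynamics of single tonically firing
neurons. The optical physics is deliberately out of scope: illumination is
abstracted as a photothermal temperature forcing ΔT(t) acting on
conductance-based membrane models, which is the working hypothesis the
analysis is built to probe.

## Neuron models

Three deterministic ODE models are provided.

**Hodgkin–Huxley (`hh`).** The canonical squid-axon model in the modern
−65 mV convention (Cm = 1 µF/cm², gNa = 120, gK = 36, gL = 0.3 mS/cm²,
canonical α/β rate functions). Each gate carries a kinetic scale factor φ̄
multiplying its total relaxation rate; these are the handles temperature
acts on. At the default drive (Iinj = 10 µA/cm²) the model fires tonically
with ≈1.5 ms half-width spikes.

**Cerebral giant cell (`cgc`).** A six-current single compartment for the
*Lymnaea stagnalis* CGC neuron with its characteristic shoulder-shaped
(calcium-dependent plateau) spike:

    Cm dV/dt = Iinj − INaT − INaP − IA − ID − ILVA − IHVA
    INaT = gNaT·m∞³·h·(V−ENa)      INaP = gNaP·r³·(V−ENa)
    IA   = gA·a⁴·b·(V−EK)          ID   = gD·n⁴·(V−EK)
    ILVA = gLVA·c∞³·d∞·(V−ECa)     IHVA = gHVA·e³·f·(V−ECa)

m∞, c∞ and d∞ are instantaneous (algebraic in V); the remaining gates obey
first-order kinetics dx/dt = φ̄x·(x∞(V) − x)/τx(V). The Boltzmann steady
states and time constants are this package's own calibration (they are
recorded with comments in `models/parameters/cgc.yaml` and `models/cgc.py`):
the target features were tonic pacemaking carried by the persistent sodium
current (no explicit leak term), a broad spike (half-width ≈ 43 ms at
nominal parameters, amplitude ≈ 112 mV, ISI ≈ 262 ms), a dV/dt inflection
on the repolarization limb produced by the high-voltage-activated calcium
current, and spike narrowing with rising temperature under Q10 = 3. The
calibration was frozen once these qualitative properties held; none of the
downstream statistics are fitted to it.

**Two-compartment N3t (`n3t`).** Slow somatic and fast axonal dynamics are
segregated into two electrically coupled compartments (τm·k dV/dt form,
currents in voltage units). The soma carries leak plus a slow low-threshold
calcium-like current iT = gT·p²·q·(VS−ECa) and receives the injected drive
(the axonal entry `iinjA` is exposed because either compartment is a
legitimate injection site); the axon carries the fast iNaT/iK spiking pair.
The synaptic current defaults to zero — an isolated cell is modelled. The
per-compartment capacitance scale factors kS and kA are the handles of the
capacitance studies.

**Integration.** Fixed-step 4th-order Runge–Kutta, default dt = 0.01 ms,
recorded at 0.1 ms (the 10 kHz acquisition grid). The scheme is
deterministic and reproducible; an acceptance test checks that spike times
agree with a 10× finer step within 0.1 ms over 5 s for all three models.
Gating variables are clamped to [0, 1] only for numerical overshoot below
1e−9 — anything larger aborts with the step index, as does |V| > 500 mV.
Before every experiment the model is pre-integrated for 2 s with zero
injected current, which removes transient-dependent metric bias.

## Temperature dependence

Maximal conductances and gate kinetic factors follow the Q10 law
g(T) = ḡ·Q10^((T−T0)/10) (and identically for φ̄); capacitance is linear,
C(T) = c0·(1 + γ·(T−T0)) with γ = 0.05 /°C. Q10 = 3 is the default for
every channel and gate — a mid-range literature value — and each element
carries its own Q10 and an independent enable flag so that exclusion
studies ("only one channel temperature-dependent" / "all but one") are a
matter of flag algebra. Note that because every dynamical gate here is
written in the x∞/τ form, applying Q10 to the relaxation rate and applying
it to the time constant are the same operation; no separate convention is
needed. Temperature enters the integrator through effective parameters
recomputed every step, so ΔT may vary during a simulation.

Heating protocols: a constant offset inside a window (sustained
illumination at steady state — the default for sustained-stimulation
analyses), first-order kinetics with τ_heat (transient illumination through
a shutter), and piecewise-constant schedules. The kinetic defaults,
ΔT_ss ≈ 1.5 °C and τ_heat = 700 ms, are chosen so the rise reaches ≈0.1 °C
at 50 ms, consistent with open-pipette estimates of bath heating under
~90 mW CW-NIR illumination; both are configuration values because membrane
heating plausibly exceeds the bath estimate.

## Waveform metrics

Spikes are detected as local maxima above an absolute threshold (default
0 mV) separated by a refractory interval (default 50 ms; per-model defaults
adapt to faster firing), excluding peaks within 100 ms of the trace edges
so the ±100 ms segment always fits. Four metrics per spike:

* **duration** — time between the two half-height crossings flanking the
  peak; half-height is referenced to the segment minimum (amplitude is
  defined min-to-max), and crossings are located by linear interpolation;
* **amplitude** — max − min over the segment;
* **depolarization / repolarization slope** — the two-point difference
  (V(t+1 ms) − V(t−1 ms))/2 ms at the rising / falling half-height
  crossing; slopes are stored signed and compared by magnitude in the
  change statistics.

A stereotypy filter removes spikes whose normalized-duration z-score falls
below a cutoff. The default cutoff (−0.1) is kept configurable and should
be used knowingly: a −0.1 cutoff removes roughly 46% of a symmetric
distribution, so it is only appropriate when the duration distribution is
strongly left-skewed by waveform glitches.

## Change statistics

All changes are dimensionless fractions (×100 for display). Per experiment
and metric, the experimental change is |μ_laser − μ_control|/|μ_control|;
per parameter sweep, the model change is |min − max|/|max| over the grid.
The across-experiment mean ± SD of the experimental change (MEC) defines a
similarity range (μMEC ± 2σMEC) onto which a model change is mapped
affinely — score 0 at Vmin = max(0, μMEC − 2σMEC), 1 at Vmax = μMEC + 2σMEC
— with an in-range flag. Significance uses two-sided paired t-tests on
per-experiment means (pairing on spikes would pseudo-replicate) for
control-vs-laser and control-vs-recovery, with a Bonferroni-corrected
high-significance threshold of 0.01/4 across the four metrics; identical
pairs yield p = 1. Firing-rate analysis computes the absolute firing rate
(spike count / trial duration), classifies the laser trial as excitation /
inhibition / no-change with a ±10% relative-change rule, gates inclusion on
the recovery returning within 10% of control, and builds ISI histograms on
bin edges shared across the triplet (default 50 ms bins).

## Parameter sweeps

One candidate is swept at a time: capacitance (0.5–1.5× nominal, 11 steps),
a single maximal conductance (0.25–2× nominal, 15 steps), or ΔT (0–10 °C,
1 °C steps) with all enabled parameters Q10-scaled. Default simulation
length is 10 s per grid point with the first 2 s discarded; a grid point
must retain at least 5 detected spikes to count as viable (tonic spiking is
the exploration criterion), and changes are computed over viable points
only. The channel-dependency study re-runs the ΔT comparison with each
channel (and its gates) either the only temperature-dependent element or
the only temperature-independent one. `match_temperature` inverts the
ΔT-sweep curves: it interpolates the signed relative-change curves on a
fine ΔT grid and returns the least-squares match to a measured four-metric
change vector.

## Closed-loop protocol

The activity-dependent protocol is emulated sample-by-sample on a 0.1 ms
clock shared by the integrator and the predictor, so no decision can use
future samples. The spike predictor runs in two modes: a voltage threshold
updated at every peak to V(t_peak[i−1] − τ), and a voltage-area
accumulator, reset at each post-spike minimum (running minimum with a 2 mV
hysteresis), that integrates (V − V_min_ref)·Δt and triggers at a threshold
predicted from the previous cycle's area trajectory. The literal raw-sum
variant (accumulating unreferenced voltage, which in mV is negative and
grows downward) is retained behind a flag for fidelity, but the
baseline-referenced integral is the default because it makes the threshold
semantics monotone. The shutter opens 8 ms after the trigger for 58 ms;
while open, ΔT relaxes toward ΔT_ss with τ_heat = 700 ms and decays
symmetrically after closing. The lead time is solved from the requested
offset (τ = delay + duration − offset); for target offsets later than
−(delay+duration) the trigger is scheduled after the detected peak instead
of from a threshold crossing. The illumination offset is recorded as
end-of-illumination minus associated spike peak (negative when the window
ends before the peak), the associated peak being one inside the window, or
else the nearest; realized offsets are measured, never assumed. Offset
analysis bins events (default 20 ms bins over [−100, +80] ms), reports each
bin's metric change from a control reference, optionally min–max normalized
between control (0) and sustained-laser (1) references, and returns the
argmax bin per metric.

## Synthetic recordings

The generator replaces the intracellular recordings with model-based
material whose statistical structure the analysis assumes: 10 kHz sampling,
trials of 60 s by default (1–3 min is the realistic range), two
morphologies — "shoulder" (CGC nominal) and "symmetrical" (HH with
φ̄ = 0.1 and Cm×10, an exact 10-fold time rescale giving ≈15 ms half-width
at molluscan pace, preserving the shoulder > symmetrical duration
ordering). ISI variability comes from an Ornstein–Uhlenbeck fluctuation of
the injected current (τ = 500 ms, σ per type, held piecewise-constant over
50 ms update blocks), so waveform and timing covary; recording noise is
additive Gaussian (σ = 0.5 mV, chosen to challenge rather than defeat
detection); baseline drift is a slow sinusoid (≤2 mV). Triplets share model
parameters across control/laser/recovery and differ only in noise
substreams and the laser trial's thermal forcing (constant mode by
default). Batteries draw per-experiment conductance jitter from a
mean-preserving log-normal (CV = 0.1 default; the CGC pacemaker conductance
gNaP at CV/4 because firing rate is exquisitely sensitive to it) and record
a manifest from which every trace regenerates bit-exactly.

What the generator does *not* emulate: electrode artifacts, bridge
imbalance, synaptic/circuit feedback, bursting regimes, or any direct
(non-thermal) photochemical effect. Passing tests therefore demonstrate
that the analysis chain is correct and well calibrated under the stated
generative model — not that real recordings obey it.

## Numerical choices and problem sizes

Simulated problem sizes in the test suite and acceptance script are chosen
as the smallest that leave the measured quantities stable: 5 s runs for
integrator convergence, 10 s per temperature-sweep grid point, 15 s trials
for triplet-based ΔT recovery, 10 stimulations per offset target in the
closed-loop battery, and 10⁴ replicates for the type-I-error calibration.
Ties in half-height crossing detection are broken toward the crossing
nearest the peak (the scan runs outward from the peak); degenerate inputs
(flat segments, missing crossings, zero control means, fewer than two
pairs) raise errors naming the offending quantity.

## Known limitations

* The CGC and N3t gate kinetics are calibrated, not fitted to voltage-clamp
  data; quantitative metric values (e.g. the exact half-width) are
  therefore model-specific, and only relations between changes are
  meaningful for comparison with experiments.
* The thermal model is a single well-mixed compartment; no spatial heat
  diffusion or optical absorption physics.
* The closed-loop shutter is a pure delay + fixed window; mechanical
  jitter is not modelled.
* Multi-neuron circuits and synaptic feedback are out of scope, so
  firing-rate inhibition through network effects cannot arise here.
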