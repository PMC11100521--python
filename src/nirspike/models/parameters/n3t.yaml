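# N3t two-compartment model, Lymnaea stagnalis buccal ganglion.
# Slow soma (leak + low-threshold calcium-like iT) electrically coupled to a
# fast axon (iNaT + iK). Currents are in voltage units (conductances relative
# to leak); tau_m sets the membrane time scale and kS/kA are per-compartment
# capacitance scale factors (the capacitance-study handles).
# Calibrated in-package for sustained tonic spiking under somatic drive.
parameters:
  kS: 1.0          # soma capacitance scale
  kA: 1.0          # axon capacitance scale
  tau_m: 8.0       # membrane time constant, ms
  iinj: 40.0       # somatic drive (voltage units, mV)
  iinjA: 0.0       # optional axonal drive
  lamS: 1.0        # soma leak scale
  lamA: 1.0        # axon leak scale
  gT: 1.2          # low-threshold calcium-like conductance (soma)
  gec: 1.0         # electrical coupling conductance
  gNa: 90.0        # axonal transient sodium
  gK: 18.0         # axonal delayed rectifier
  gsyn: 0.0        # synaptic input disabled (isolated cell)
  ELS: -62.0
  ELA: -62.0
  ENa: 55.0
  EK: -90.0
  ECa: 80.0
  Esyn: -70.0
  phi_p: 1.0
  phi_q: 1.0
  phi_h: 1.0
  phi_n: 1.0
initial_state:
  VS: -62.0
  VA: -62.0
  p: 0.12
  q: 0.38
  h: 0.92
  n: 0.02
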