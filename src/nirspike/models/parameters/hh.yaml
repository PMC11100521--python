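# Hodgkin-Huxley squid-axon model, canonical 1952 parameter set expressed in
# the modern convention (resting potential near -65 mV).
# Units: capacitance uF/cm2, conductances mS/cm2, potentials mV,
# currents uA/cm2, kinetic factors dimensionless.
parameters:
  Cm: 1.0          # membrane capacitance
  Iinj: 10.0       # suprathreshold constant drive -> sustained tonic spiking
  gNa: 120.0       # transient sodium maximal conductance
  gK: 36.0         # delayed-rectifier potassium maximal conductance
  gL: 0.3          # leak conductance
  ENa: 50.0
  EK: -77.0
  EL: -54.387      # leak reversal chosen so V_rest ~= -65 mV at Iinj = 0
  phi_m: 1.0       # per-gate kinetic scale factors (Q10 acts on these)
  phi_h: 1.0
  phi_n: 1.0
initial_state:
  V: -65.0
  m: 0.0529        # steady-state gate values at -65 mV
  h: 0.5961
  n: 0.3177
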