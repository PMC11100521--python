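# CGC (cerebral giant cell) model, Lymnaea stagnalis, shoulder-type spike.
# Six-current single compartment; gate kinetic shapes live in cgc.py.
# Conductance balance calibrated in-package so the cell fires tonically at
# ~1-2 Hz with a broad (tens of ms) half-width spike, a calcium-dependent
# shoulder on the repolarization limb, and temperature narrowing under Q10=3.
# Units: uF/cm2, mS/cm2, mV, uA/cm2.
parameters:
  Cm: 1.0
  Iinj: 0.0        # pacemaking is carried by the persistent sodium current
  gNaT: 4.0        # transient sodium
  gNaP: 0.035       # persistent sodium (pacemaker)
  gA: 3.0          # A-type potassium
  gD: 2.0          # delayed-rectifier potassium
  gLVA: 0.08       # low-voltage-activated calcium
  gHVA: 0.6       # high-voltage-activated calcium (shoulder)
  ENa: 55.0
  EK: -90.0
  ECa: 80.0
  phi_h: 1.0       # kinetic scale factors per dynamical gate
  phi_r: 1.0
  phi_a: 1.0
  phi_b: 1.0
  phi_n: 1.0
  phi_e: 1.0
  phi_f: 1.0
initial_state:
  V: -49.24
  h: 0.899
  r: 0.404
  a: 0.077
  b: 0.479
  n: 0.107
  e: 0.005
  f: 0.755
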