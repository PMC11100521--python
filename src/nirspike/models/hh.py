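"""Classic Hodgkin–Huxley squid-axon model (modern −65 mV convention).

Membrane equation:  Cm dV/dt = Iinj − INa − IK − IL with
INa = gNa·m³·h·(V−ENa), IK = gK·n⁴·(V−EK), IL = gL·(V−EL).

Gate kinetics use the canonical 1952 α/β rate functions; the per-gate
kinetic factors φ̄ multiply the total relaxation rate and are the handles
the Q10 temperature law acts on. With φ̄ = 1 the model reproduces the
textbook dynamics (≈2 ms spikes); the synthetic symmetrical-spike neuron
uses φ̄ ≈ 0.1 to slow the kinetics to molluscan time scales.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import ConductanceModel

__all__ = ["HodgkinHuxley"]

# parameter vector layout
_P = ("Cm", "Iinj", "gNa", "gK", "gL", "ENa", "EK", "EL",
      "phi_m", "phi_h", "phi_n")


@njit(cache=True)
def _vtrap(x):
    # x / (1 - exp(-x)), stable near x = 0
    if abs(x) < 1e-7:
        return 1.0 + 0.5 * x
    return x / (1.0 - np.exp(-x))


@njit(cache=True)
def alpha_m(V):
    return _vtrap((V + 40.0) / 10.0)


@njit(cache=True)
def beta_m(V):
    return 4.0 * np.exp(-(V + 65.0) / 18.0)


@njit(cache=True)
def alpha_h(V):
    return 0.07 * np.exp(-(V + 65.0) / 20.0)


@njit(cache=True)
def beta_h(V):
    return 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


@njit(cache=True)
def alpha_n(V):
    return 0.1 * _vtrap((V + 55.0) / 10.0)


@njit(cache=True)
def beta_n(V):
    return 0.125 * np.exp(-(V + 65.0) / 80.0)


@njit(cache=True)
def _rhs_hh(t, y, p, dy):
    V, m, h, n = y[0], y[1], y[2], y[3]
    Cm, Iinj = p[0], p[1]
    gNa, gK, gL = p[2], p[3], p[4]
    ENa, EK, EL = p[5], p[6], p[7]
    INa = gNa * m ** 3 * h * (V - ENa)
    IK = gK * n ** 4 * (V - EK)
    IL = gL * (V - EL)
    dy[0] = (Iinj - INa - IK - IL) / Cm
    dy[1] = p[8] * (alpha_m(V) * (1.0 - m) - beta_m(V) * m)
    dy[2] = p[9] * (alpha_h(V) * (1.0 - h) - beta_h(V) * h)
    dy[3] = p[10] * (alpha_n(V) * (1.0 - n) - beta_n(V) * n)


class HodgkinHuxley(ConductanceModel):
    name = "hh"
    state_names = ("V", "m", "h", "n")
    param_names = _P
    detection_refractory_ms = 10.0
    primary_voltage = "V"
    voltage_states = ("V",)
    conductance_channel = {"gNa": "Na", "gK": "K", "gL": "L"}
    rate_gate = {"phi_m": "m", "phi_h": "h", "phi_n": "n"}
    capacitance_params = ("Cm",)
    channels = ("Na", "K", "L")
    channel_gates = {"Na": ("m", "h"), "K": ("n",), "L": ()}
    current_names = ("INa", "IK", "IL")
    _rhs = _rhs_hh

    def _currents(self, y, p):
        V, m, h, n = y
        return {
            "INa": p["gNa"] * m ** 3 * h * (V - p["ENa"]),
            "IK": p["gK"] * n ** 4 * (V - p["EK"]),
            "IL": p["gL"] * (V - p["EL"]),
        }
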