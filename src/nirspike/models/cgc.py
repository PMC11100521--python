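"""Cerebral giant cell (CGC) model — *Lymnaea stagnalis*, shoulder-type spike.

Six ionic currents shape the broad, shoulder-bearing action potential:

    INaT  = gNaT · m∞³ · h · (V − ENa)   transient sodium (m instantaneous)
    INaP  = gNaP · r³  · (V − ENa)       persistent sodium (pacemaker drive)
    IA    = gA · a⁴ · b · (V − EK)       transient (A-type) potassium
    ID    = gD · n⁴ · (V − EK)           delayed-rectifier potassium
    ILVA  = gLVA · c∞³ · d∞ · (V − ECa)  low-voltage-activated calcium
    IHVA  = gHVA · e³ · f · (V − ECa)    high-voltage-activated calcium

with Cm dV/dt = Iinj − INaT − INaP − IA − ID − ILVA − IHVA (no separate
leak; the persistent currents set the resting behaviour). Dynamical gates
follow dx/dt = φ̄x·(x∞(V) − x)/τx(V); m∞, c∞ and d∞ are algebraic in V.

Steady states are Boltzmann functions and time constants smooth sigmoids,
calibrated so the model fires tonically at ~1–2 Hz with a 30–50 ms
half-width spike whose repolarization carries the calcium-dependent
shoulder, and narrows as temperature rises under the Q10 = 3 law.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import ConductanceModel

__all__ = ["CGC"]

_P = ("Cm", "Iinj", "gNaT", "gNaP", "gA", "gD", "gLVA", "gHVA",
      "ENa", "EK", "ECa",
      "phi_h", "phi_r", "phi_a", "phi_b", "phi_n", "phi_e", "phi_f")


@njit(cache=True)
def _sig(V, Vh, k):
    # Boltzmann steady state; k > 0 activates with depolarization
    return 1.0 / (1.0 + np.exp(-(V - Vh) / k))


@njit(cache=True)
def m_inf(V):
    return _sig(V, -25.0, 5.0)


@njit(cache=True)
def h_inf(V):
    return _sig(V, -40.0, -5.0)


@njit(cache=True)
def tau_h(V):
    return 15.0 + 35.0 * _sig(V, -35.0, -6.0)


@njit(cache=True)
def r_inf(V):
    return _sig(V, -52.0, 6.0)


@njit(cache=True)
def tau_r(V):
    return 60.0


@njit(cache=True)
def a_inf(V):
    return _sig(V, -30.0, 8.0)


@njit(cache=True)
def tau_a(V):
    return 3.0


@njit(cache=True)
def b_inf(V):
    return _sig(V, -55.0, -5.0)


@njit(cache=True)
def tau_b(V):
    return 40.0


@njit(cache=True)
def n_inf(V):
    return _sig(V, -30.0, 9.0)


@njit(cache=True)
def tau_n(V):
    return 60.0


@njit(cache=True)
def c_inf(V):
    return _sig(V, -45.0, 5.0)


@njit(cache=True)
def d_inf(V):
    return _sig(V, -65.0, -6.0)


@njit(cache=True)
def e_inf(V):
    return _sig(V, -25.0, 5.0)


@njit(cache=True)
def tau_e(V):
    return 20.0


@njit(cache=True)
def f_inf(V):
    return _sig(V, -30.0, -8.0)


@njit(cache=True)
def tau_f(V):
    return 300.0


@njit(cache=True)
def _rhs_cgc(t, y, p, dy):
    V = y[0]
    h, r, a, b, n, e, f = y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    Cm, Iinj = p[0], p[1]
    gNaT, gNaP, gA, gD, gLVA, gHVA = p[2], p[3], p[4], p[5], p[6], p[7]
    ENa, EK, ECa = p[8], p[9], p[10]
    mi = m_inf(V)
    INaT = gNaT * mi ** 3 * h * (V - ENa)
    INaP = gNaP * r ** 3 * (V - ENa)
    IA = gA * a ** 4 * b * (V - EK)
    ID = gD * n ** 4 * (V - EK)
    ILVA = gLVA * c_inf(V) ** 3 * d_inf(V) * (V - ECa)
    IHVA = gHVA * e ** 3 * f * (V - ECa)
    dy[0] = (Iinj - INaT - INaP - IA - ID - ILVA - IHVA) / Cm
    dy[1] = p[11] * (h_inf(V) - h) / tau_h(V)
    dy[2] = p[12] * (r_inf(V) - r) / tau_r(V)
    dy[3] = p[13] * (a_inf(V) - a) / tau_a(V)
    dy[4] = p[14] * (b_inf(V) - b) / tau_b(V)
    dy[5] = p[15] * (n_inf(V) - n) / tau_n(V)
    dy[6] = p[16] * (e_inf(V) - e) / tau_e(V)
    dy[7] = p[17] * (f_inf(V) - f) / tau_f(V)


class CGC(ConductanceModel):
    name = "cgc"
    state_names = ("V", "h", "r", "a", "b", "n", "e", "f")
    param_names = _P
    primary_voltage = "V"
    voltage_states = ("V",)
    conductance_channel = {"gNaT": "NaT", "gNaP": "NaP", "gA": "A",
                           "gD": "D", "gLVA": "LVA", "gHVA": "HVA"}
    rate_gate = {"phi_h": "h", "phi_r": "r", "phi_a": "a", "phi_b": "b",
                 "phi_n": "n", "phi_e": "e", "phi_f": "f"}
    capacitance_params = ("Cm",)
    channels = ("NaT", "NaP", "A", "D", "LVA", "HVA")
    channel_gates = {"NaT": ("h",), "NaP": ("r",), "A": ("a", "b"),
                     "D": ("n",), "LVA": (), "HVA": ("e", "f")}
    current_names = ("INaT", "INaP", "IA", "ID", "ILVA", "IHVA")
    _rhs = _rhs_cgc

    def _currents(self, y, p):
        V = y[0]
        h, r, a, b, n, e, f = y[1:]
        return {
            "INaT": p["gNaT"] * float(m_inf(V)) ** 3 * h * (V - p["ENa"]),
            "INaP": p["gNaP"] * r ** 3 * (V - p["ENa"]),
            "IA": p["gA"] * a ** 4 * b * (V - p["EK"]),
            "ID": p["gD"] * n ** 4 * (V - p["EK"]),
            "ILVA": p["gLVA"] * float(c_inf(V)) ** 3 * float(d_inf(V)) * (V - p["ECa"]),
            "IHVA": p["gHVA"] * e ** 3 * f * (V - p["ECa"]),
        }

    def steady_gates(self, V: float) -> dict:
        """Steady-state values of the dynamical gates at voltage V."""
        return {"h": float(h_inf(V)), "r": float(r_inf(V)), "a": float(a_inf(V)),
                "b": float(b_inf(V)), "n": float(n_inf(V)), "e": float(e_inf(V)),
                "f": float(f_inf(V))}
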