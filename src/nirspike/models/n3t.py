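"""Two-compartment N3t model — *Lymnaea stagnalis* buccal-ganglion neuron.

The slow (somatic) and fast (axonal) dynamics are segregated into two
electrically coupled compartments governed by

    τm·kS dVS/dt = iinj − iL,S − iT − iec,S − isyn
    τm·kA dVA/dt =       − iL,A − iNaT − iK − iec,A

where the currents are in voltage units (conductances relative to leak):
iL = λ(V − EL), the soma carries a low-threshold transient calcium-like
current iT = gT·p²·q·(VS − ECa), the axon the spiking pair
iNaT = gNa·m∞³·h·(VA − ENa) and iK = gK·n⁴·(VA − EK), and the compartments
couple through iec = gec·(V − V_other). The synaptic current isyn defaults
to zero (isolated-cell study). kS and kA are per-compartment capacitance
scale factors — the handles of the capacitance studies; iinj targets the
soma by default with an axonal entry available (iinjA).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import ConductanceModel

__all__ = ["N3t"]

_P = ("kS", "kA", "tau_m", "iinj", "iinjA",
      "lamS", "lamA", "gT", "gec", "gNa", "gK", "gsyn",
      "ELS", "ELA", "ENa", "EK", "ECa", "Esyn",
      "phi_p", "phi_q", "phi_h", "phi_n")


@njit(cache=True)
def _sig(V, Vh, k):
    return 1.0 / (1.0 + np.exp(-(V - Vh) / k))


@njit(cache=True)
def m_inf(V):
    return _sig(V, -35.0, 5.0)


@njit(cache=True)
def h_inf(V):
    return _sig(V, -40.0, -6.0)


@njit(cache=True)
def tau_h(V):
    return 3.0 + 5.0 * _sig(V, -40.0, -5.0)


@njit(cache=True)
def n_inf(V):
    return _sig(V, -30.0, 8.0)


@njit(cache=True)
def tau_n(V):
    return 4.0


@njit(cache=True)
def p_inf(V):
    return _sig(V, -50.0, 6.0)


@njit(cache=True)
def tau_p(V):
    return 40.0


@njit(cache=True)
def q_inf(V):
    return _sig(V, -65.0, -6.0)


@njit(cache=True)
def tau_q(V):
    return 250.0


@njit(cache=True)
def _rhs_n3t(t, y, p, dy):
    VS, VA = y[0], y[1]
    pg, qg, h, n = y[2], y[3], y[4], y[5]
    kS, kA, tau_m = p[0], p[1], p[2]
    iinj, iinjA = p[3], p[4]
    lamS, lamA, gT, gec, gNa, gK, gsyn = p[5], p[6], p[7], p[8], p[9], p[10], p[11]
    ELS, ELA, ENa, EK, ECa, Esyn = p[12], p[13], p[14], p[15], p[16], p[17]
    iLS = lamS * (VS - ELS)
    iT = gT * pg ** 2 * qg * (VS - ECa)
    iecS = gec * (VS - VA)
    isyn = gsyn * (VS - Esyn)
    iLA = lamA * (VA - ELA)
    iNaT = gNa * m_inf(VA) ** 3 * h * (VA - ENa)
    iK = gK * n ** 4 * (VA - EK)
    iecA = gec * (VA - VS)
    dy[0] = (iinj - iLS - iT - iecS - isyn) / (tau_m * kS)
    dy[1] = (iinjA - iLA - iNaT - iK - iecA) / (tau_m * kA)
    dy[2] = p[18] * (p_inf(VS) - pg) / tau_p(VS)
    dy[3] = p[19] * (q_inf(VS) - qg) / tau_q(VS)
    dy[4] = p[20] * (h_inf(VA) - h) / tau_h(VA)
    dy[5] = p[21] * (n_inf(VA) - n) / tau_n(VA)


class N3t(ConductanceModel):
    name = "n3t"
    state_names = ("VS", "VA", "p", "q", "h", "n")
    param_names = _P
    detection_refractory_ms = 15.0
    primary_voltage = "VA"
    voltage_states = ("VS", "VA")
    conductance_channel = {"lamS": "LS", "lamA": "LA", "gT": "T",
                           "gec": "ec", "gNa": "NaT", "gK": "K"}
    rate_gate = {"phi_p": "p", "phi_q": "q", "phi_h": "h", "phi_n": "n"}
    capacitance_params = ("kS", "kA")
    channels = ("LS", "LA", "T", "ec", "NaT", "K")
    channel_gates = {"LS": (), "LA": (), "T": ("p", "q"),
                     "ec": (), "NaT": ("h",), "K": ("n",)}
    current_names = ("iL_S", "iT", "iec_S", "isyn", "iL_A", "iNaT", "iK", "iec_A")
    _rhs = _rhs_n3t

    def _currents(self, y, p):
        VS, VA = y[0], y[1]
        pg, qg, h, n = y[2], y[3], y[4], y[5]
        return {
            "iL_S": p["lamS"] * (VS - p["ELS"]),
            "iT": p["gT"] * pg ** 2 * qg * (VS - p["ECa"]),
            "iec_S": p["gec"] * (VS - VA),
            "isyn": p["gsyn"] * (VS - p["Esyn"]),
            "iL_A": p["lamA"] * (VA - p["ELA"]),
            "iNaT": p["gNa"] * float(m_inf(VA)) ** 3 * h * (VA - p["ENa"]),
            "iK": p["gK"] * n ** 4 * (VA - p["EK"]),
            "iec_A": p["gec"] * (VA - VS),
        }

    def _injection_params(self) -> tuple:
        return ("iinj", "iinjA")
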