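"""Temperature dependence of membrane parameters and heating protocols.

Photothermal stimulation is abstracted as a temperature forcing ΔT(t) on the
conductance-based models. Maximal conductances and gate kinetic factors scale
with the classic Q10 law,

    g(T)   = ḡ · Q10^((T − T0)/10)
    φ(T)   = φ̄ · Q10^((T − T0)/10)

and membrane capacitance varies linearly,

    C(T)   = c0 · (1 + γ·(T − T0)),      γ = 0.05 /°C by default.

Every channel conductance and every dynamical gate carries its own Q10 value
and an independent enable flag, which supports exclusion studies where the
temperature dependence of a single channel is switched off (or is the only
one switched on).

Heating protocols come in three flavours: a constant offset inside a time
window (sustained illumination at steady state), first-order kinetics with a
heating time constant (transient illumination through a shutter), and an
arbitrary piecewise-constant schedule. The kinetic defaults — steady-state
rise 1.5 °C with τ = 700 ms, so that only ≈0.1 °C is reached after 50 ms —
match open-pipette estimates of bath heating under continuous-wave
near-infrared illumination at ~90 mW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Q10Settings",
    "TemperatureProtocol",
    "scale_conductance",
    "scale_rate",
    "capacitance_at_T",
    "temperature_at",
]

DEFAULT_Q10 = 3.0  # common literature value for channel conductances and kinetics
DEFAULT_GAMMA = 0.05  # fractional capacitance change per °C
DEFAULT_T0 = 23.0  # °C, bath temperature the nominal parameters refer to


def scale_conductance(g: float, q10: float, T: float, T0: float) -> float:
    """Q10-scaled maximal conductance at temperature ``T``."""
    if not q10 > 0:
        raise ValueError("Q10 must be positive")
    return g * q10 ** ((T - T0) / 10.0)


def scale_rate(phi: float, q10: float, T: float, T0: float) -> float:
    """Q10-scaled kinetic factor at temperature ``T``.

    The factor multiplies the gate relaxation rate (x∞ − x)/τx; multiplying
    the rate by φ and dividing τx by φ are the same operation, so a single
    convention covers both readings.
    """
    if not q10 > 0:
        raise ValueError("Q10 must be positive")
    return phi * q10 ** ((T - T0) / 10.0)


def capacitance_at_T(c0: float, gamma: float, T: float, T0: float) -> float:
    """Linearly temperature-dependent capacitance c0·(1 + γ·(T − T0))."""
    if not c0 > 0:
        raise ValueError("capacitance must be positive")
    c = c0 * (1.0 + gamma * (T - T0))
    if c <= 0:
        raise ValueError(f"capacitance became non-positive ({c:g}) at T={T:g} °C")
    return c


@dataclass
class Q10Settings:
    """Per-channel and per-gate temperature sensitivities with enable flags.

    ``q10_conductance`` maps channel names (model-specific, e.g. ``"NaT"`` or
    ``"Na"``) to Q10 values; ``q10_gate`` maps dynamical gate names (e.g.
    ``"h"``, ``"n"``). Channels/gates absent from the mappings use
    ``default_q10``. A flag set to False freezes that element at its nominal
    value regardless of temperature.
    """

    default_q10: float = DEFAULT_Q10
    q10_conductance: Mapping[str, float] = field(default_factory=dict)
    q10_gate: Mapping[str, float] = field(default_factory=dict)
    gamma: float = DEFAULT_GAMMA
    T0: float = DEFAULT_T0
    conductance_enabled: Mapping[str, bool] = field(default_factory=dict)
    gate_enabled: Mapping[str, bool] = field(default_factory=dict)
    capacitance_enabled: bool = True

    def conductance_q10(self, channel: str) -> float:
        if not self.conductance_enabled.get(channel, True):
            return 1.0
        q = float(self.q10_conductance.get(channel, self.default_q10))
        if not q > 0:
            raise ValueError(f"Q10 for channel {channel!r} must be positive")
        return q

    def gate_q10(self, gate: str) -> float:
        if not self.gate_enabled.get(gate, True):
            return 1.0
        q = float(self.q10_gate.get(gate, self.default_q10))
        if not q > 0:
            raise ValueError(f"Q10 for gate {gate!r} must be positive")
        return q

    def effective_gamma(self) -> float:
        return self.gamma if self.capacitance_enabled else 0.0

    # --- flag algebra used by the channel-dependency studies -----------------
    def with_only(self, channels: Sequence[str], gates: Sequence[str],
                  capacitance: bool = False) -> "Q10Settings":
        """Settings where only the named elements are temperature dependent."""
        return replace(
            self,
            conductance_enabled={**dict.fromkeys(self.conductance_enabled, False),
                                 **{c: True for c in channels}},
            gate_enabled={**dict.fromkeys(self.gate_enabled, False),
                          **{g: True for g in gates}},
            capacitance_enabled=capacitance,
        )

    def with_disabled(self, channels: Sequence[str] = (), gates: Sequence[str] = (),
                      capacitance: bool = False) -> "Q10Settings":
        """Settings with the named elements' temperature dependence removed."""
        return replace(
            self,
            conductance_enabled={**self.conductance_enabled,
                                 **{c: False for c in channels}},
            gate_enabled={**self.gate_enabled, **{g: False for g in gates}},
            capacitance_enabled=False if capacitance else self.capacitance_enabled,
        )


@dataclass
class TemperatureProtocol:
    """Temperature forcing ΔT(t) on top of a baseline T0.

    Modes
    -----
    ``"off"``
        ΔT = 0 everywhere (control trial).
    ``"constant"``
        ΔT = ΔT_ss inside [t_on, t_off), 0 outside (sustained illumination at
        its steady state).
    ``"kinetic"``
        first-order rise toward ΔT_ss during [t_on, t_off) with time constant
        τ_heat, and symmetric first-order decay after t_off.
    ``"schedule"``
        piecewise-constant ΔT given by ``schedule_times``/``schedule_values``
        (right-open steps; ΔT is 0 before the first breakpoint).
    """

    mode: str = "off"
    T0: float = DEFAULT_T0
    dT_ss: float = 0.0
    t_on_ms: float = 0.0
    t_off_ms: float = float("inf")
    tau_heat_ms: float = 700.0
    schedule_times: np.ndarray | None = None
    schedule_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("off", "constant", "kinetic", "schedule"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.dT_ss < 0:
            raise ValueError("ΔT_ss must be non-negative")
        if self.mode == "kinetic" and not self.tau_heat_ms > 0:
            raise ValueError("heating time constant must be positive")
        if self.mode == "schedule":
            t = np.asarray(self.schedule_times, dtype=float)
            v = np.asarray(self.schedule_values, dtype=float)
            if t.ndim != 1 or t.shape != v.shape or t.size == 0:
                raise ValueError("schedule needs matching 1-D times and values")
            if np.any(np.diff(t) <= 0):
                raise ValueError("schedule times must be strictly increasing")
            if np.any(v < 0):
                raise ValueError("schedule ΔT values must be non-negative")
            self.schedule_times = t
            self.schedule_values = v

    def delta_T(self, t_ms):
        """ΔT(t) in °C; accepts scalars or arrays."""
        t = np.asarray(t_ms, dtype=float)
        if self.mode == "off":
            out = np.zeros_like(t)
        elif self.mode == "constant":
            out = np.where((t >= self.t_on_ms) & (t < self.t_off_ms), self.dT_ss, 0.0)
        elif self.mode == "kinetic":
            out = np.zeros_like(t)
            rising = (t >= self.t_on_ms) & (t < self.t_off_ms)
            out = np.where(
                rising,
                self.dT_ss * -np.expm1(-(t - self.t_on_ms) / self.tau_heat_ms),
                out,
            )
            if np.isfinite(self.t_off_ms):
                dT_off = self.dT_ss * -math.expm1(
                    -(self.t_off_ms - self.t_on_ms) / self.tau_heat_ms
                )
                after = t >= self.t_off_ms
                out = np.where(
                    after, dT_off * np.exp(-(t - self.t_off_ms) / self.tau_heat_ms), out
                )
        else:  # schedule
            idx = np.searchsorted(self.schedule_times, t, side="right") - 1
            vals = np.concatenate([[0.0], self.schedule_values])
            out = vals[idx + 1]
        return out if out.shape else float(out)

    def temperature(self, t_ms):
        """Absolute temperature T0 + ΔT(t)."""
        return self.T0 + self.delta_T(t_ms)

    # compact numeric encoding consumed by the integrator cores
    _MODE_CODES = {"off": 0, "constant": 1, "kinetic": 2, "schedule": 3}

    def encode(self) -> tuple:
        code = self._MODE_CODES[self.mode]
        st = self.schedule_times if self.schedule_times is not None else np.empty(0)
        sv = self.schedule_values if self.schedule_values is not None else np.empty(0)
        return (code, self.dT_ss, self.t_on_ms, self.t_off_ms, self.tau_heat_ms,
                np.asarray(st, dtype=float), np.asarray(sv, dtype=float))


def temperature_at(t_ms, protocol: TemperatureProtocol):
    """Absolute temperature (°C) at time ``t_ms`` under ``protocol``."""
    return protocol.temperature(t_ms)
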