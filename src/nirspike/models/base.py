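"""Shared machinery for the conductance-based neuron models.

Each model is a deterministic ODE system dy/dt = f(y, p(T)) integrated with a
fixed-step 4th-order Runge–Kutta scheme (default dt = 0.01 ms) and recorded
on a coarser grid (default 0.1 ms, the 10 kHz acquisition grid). Temperature
enters through effective parameters recomputed at every step from the Q10
law, the linear capacitance relation and the active heating protocol, so
time-varying ΔT(t) during integration is supported.

Gating variables are clamped to [0, 1] only when numerical overshoot is
below 1e-9; larger excursions and voltage blow-up (|V| > 500 mV) abort the
integration with the offending step index.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import yaml
from numba import njit

from ..thermal import Q10Settings, TemperatureProtocol
from ..trace import VoltageTrace

__all__ = ["ConductanceModel", "SimulationResult", "IntegrationError"]

GATE_CLAMP_TOL = 1e-9
VOLTAGE_BLOWUP_MV = 500.0


class IntegrationError(RuntimeError):
    pass


@njit(cache=True)
def _delta_T(t, code, dT_ss, t_on, t_off, tau, st, sv):
    """ΔT(t) for the encoded temperature protocol (see thermal module)."""
    if code == 0:
        return 0.0
    if code == 1:
        return dT_ss if (t >= t_on) and (t < t_off) else 0.0
    if code == 2:
        if t < t_on:
            return 0.0
        if t < t_off:
            return dT_ss * (1.0 - np.exp(-(t - t_on) / tau))
        dT_off = dT_ss * (1.0 - np.exp(-(t_off - t_on) / tau))
        return dT_off * np.exp(-(t - t_off) / tau)
    # piecewise-constant schedule
    dT = 0.0
    for i in range(st.size):
        if t >= st[i]:
            dT = sv[i]
        else:
            break
    return dT


def _make_integrator(rhs):
    """Build a jitted RK4 integrator around a jitted right-hand side.

    ``rhs(t, y, p, dy)`` fills ``dy`` in place using the effective (already
    temperature-scaled) parameter vector ``p``.
    """

    @njit(cache=False)
    def integrate(y0, p, q10, capmask, gamma,
                  code, dT_ss, t_on, t_off, tau, st, sv,
                  dt, n_steps, rec_every, v_idx, g_idx):
        ny = y0.size
        npar = p.size
        n_rec = n_steps // rec_every + 1
        out_t = np.empty(n_rec)
        out_y = np.empty((n_rec, ny))
        peff = np.empty(npar)
        k1 = np.empty(ny); k2 = np.empty(ny); k3 = np.empty(ny); k4 = np.empty(ny)
        yt = np.empty(ny)
        y = y0.copy()
        gmin = np.ones(g_idx.size)
        gmax = np.zeros(g_idx.size)
        for j in range(g_idx.size):
            gmin[j] = y[g_idx[j]]
            gmax[j] = y[g_idx[j]]
        out_t[0] = 0.0
        out_y[0] = y
        last_dT = np.nan
        rec = 1
        for step in range(n_steps):
            t = step * dt
            dT = _delta_T(t, code, dT_ss, t_on, t_off, tau, st, sv)
            if dT != last_dT:
                s = dT / 10.0
                for i in range(npar):
                    if capmask[i]:
                        peff[i] = p[i] * (1.0 + gamma * dT)
                    else:
                        peff[i] = p[i] * q10[i] ** s
                last_dT = dT
            rhs(t, y, peff, k1)
            for i in range(ny):
                yt[i] = y[i] + 0.5 * dt * k1[i]
            rhs(t + 0.5 * dt, yt, peff, k2)
            for i in range(ny):
                yt[i] = y[i] + 0.5 * dt * k2[i]
            rhs(t + 0.5 * dt, yt, peff, k3)
            for i in range(ny):
                yt[i] = y[i] + dt * k3[i]
            rhs(t + dt, yt, peff, k4)
            for i in range(ny):
                y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            # gate bounds
            for j in range(g_idx.size):
                g = y[g_idx[j]]
                if g < 0.0:
                    if g < -1e-9:
                        return 1, step, out_t[:rec], out_y[:rec], gmin, gmax, y
                    g = 0.0
                    y[g_idx[j]] = 0.0
                elif g > 1.0:
                    if g > 1.0 + 1e-9:
                        return 1, step, out_t[:rec], out_y[:rec], gmin, gmax, y
                    g = 1.0
                    y[g_idx[j]] = 1.0
                if g < gmin[j]:
                    gmin[j] = g
                if g > gmax[j]:
                    gmax[j] = g
            for j in range(v_idx.size):
                if not np.isfinite(y[v_idx[j]]) or abs(y[v_idx[j]]) > 500.0:
                    return 2, step, out_t[:rec], out_y[:rec], gmin, gmax, y
            if (step + 1) % rec_every == 0:
                out_t[rec] = (step + 1) * dt
                out_y[rec] = y
                rec += 1
        return 0, n_steps, out_t[:rec], out_y[:rec], gmin, gmax, y

    return integrate


@dataclass
class SimulationResult:
    """Recorded output of one integration."""

    model: "ConductanceModel"
    times: np.ndarray          # ms, relative to integration start
    states: np.ndarray         # (n_rec, n_state)
    gate_min: np.ndarray
    gate_max: np.ndarray
    final_state: np.ndarray
    protocol: TemperatureProtocol
    t0_ms: float = 0.0

    @property
    def record_dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def voltage(self, name: str | None = None) -> np.ndarray:
        name = name or self.model.primary_voltage
        return self.states[:, self.model.state_names.index(name)]

    def trace(self, name: str | None = None) -> VoltageTrace:
        return VoltageTrace(self.voltage(name), self.record_dt, self.t0_ms)


class ConductanceModel:
    """Base class: subclasses define layout, defaults and the jitted RHS."""

    name: str = ""
    #: spike-detection defaults suited to the model's firing pattern
    detection_threshold_mv: float = 0.0
    detection_refractory_ms: float = 50.0
    state_names: tuple = ()
    param_names: tuple = ()
    primary_voltage: str = "V"
    voltage_states: tuple = ("V",)
    # thermal classification of parameters
    conductance_channel: Mapping[str, str] = {}   # param -> channel name
    rate_gate: Mapping[str, str] = {}             # param -> gate name
    capacitance_params: tuple = ()
    channels: tuple = ()
    channel_gates: Mapping[str, tuple] = {}
    current_names: tuple = ()
    _rhs: Callable = None

    def __init__(self, params: Mapping[str, float] | None = None):
        defaults = self._load_defaults()
        self.params = dict(defaults["parameters"])
        if params:
            unknown = set(params) - set(self.params)
            if unknown:
                raise KeyError(f"unknown parameters for {self.name}: {sorted(unknown)}")
            self.params.update({k: float(v) for k, v in params.items()})
        self._default_state = np.array(
            [defaults["initial_state"][s] for s in self.state_names], dtype=float
        )
        self._validate()
        self._integrator = self._get_integrator()

    # --- configuration --------------------------------------------------------
    @classmethod
    def _load_defaults(cls) -> dict:
        ref = importlib.resources.files("nirspike.models") / "parameters" / f"{cls.name}.yaml"
        with ref.open("r") as fh:
            return yaml.safe_load(fh)

    def _validate(self) -> None:
        for p in self.param_names:
            v = self.params[p]
            if not np.isfinite(v):
                raise ValueError(f"parameter {p} is not finite")
            if p in self.conductance_channel and v < 0:
                raise ValueError(f"conductance {p} must be non-negative")
            if p in self.capacitance_params and not v > 0:
                raise ValueError(f"capacitance parameter {p} must be positive")

    _integrator_cache: dict = {}

    @classmethod
    def _get_integrator(cls):
        if cls.name not in ConductanceModel._integrator_cache:
            ConductanceModel._integrator_cache[cls.name] = _make_integrator(cls._rhs)
        return ConductanceModel._integrator_cache[cls.name]

    # --- vector views ---------------------------------------------------------
    def param_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        p = dict(self.params)
        if overrides:
            p.update(overrides)
        return np.array([p[k] for k in self.param_names], dtype=float)

    def thermal_vectors(self, q10: Q10Settings | None):
        n = len(self.param_names)
        q = np.ones(n)
        capmask = np.zeros(n, dtype=np.bool_)
        gamma = 0.0
        if q10 is not None:
            for i, pname in enumerate(self.param_names):
                if pname in self.conductance_channel:
                    q[i] = q10.conductance_q10(self.conductance_channel[pname])
                elif pname in self.rate_gate:
                    q[i] = q10.gate_q10(self.rate_gate[pname])
                elif pname in self.capacitance_params:
                    capmask[i] = True
            gamma = q10.effective_gamma()
        return q, capmask, gamma

    def effective_params(self, T: float, q10: Q10Settings | None) -> dict:
        """Temperature-scaled parameter dictionary at absolute temperature T."""
        if q10 is None:
            return dict(self.params)
        dT = T - q10.T0
        q, capmask, gamma = self.thermal_vectors(q10)
        out = {}
        for i, pname in enumerate(self.param_names):
            v = self.params[pname]
            if capmask[i]:
                out[pname] = v * (1.0 + gamma * dT)
            else:
                out[pname] = v * q[i] ** (dT / 10.0)
        return out

    # --- dynamics -------------------------------------------------------------
    def derivatives(self, state: np.ndarray, params: Mapping[str, float] | None = None) -> np.ndarray:
        """State derivative at ``state`` with (already scaled) parameters."""
        y = np.asarray(state, dtype=float)
        self._check_state(y)
        p = self.param_vector(params)
        dy = np.empty_like(y)
        self.__class__._rhs(0.0, y, p, dy)
        return dy

    def currents(self, state: np.ndarray, params: Mapping[str, float] | None = None) -> dict:
        """Ionic currents (µA/cm², positive outward in the membrane equation)."""
        y = np.asarray(state, dtype=float)
        self._check_state(y)
        p = dict(self.params)
        if params:
            p.update(params)
        return self._currents(y, p)

    def _currents(self, y, p) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_state(self, y: np.ndarray) -> None:
        if y.shape != (len(self.state_names),):
            raise ValueError(
                f"{self.name} state must have {len(self.state_names)} entries")
        for nm, v in zip(self.state_names, y):
            if not np.isfinite(v):
                raise ValueError(f"non-finite state variable {nm!r}: {v}")
        for i in self.gate_indices():
            if not 0.0 <= y[i] <= 1.0:
                raise ValueError(
                    f"gating variable {self.state_names[i]!r} outside [0, 1]: {y[i]}")

    def gate_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.state_names) if s not in self.voltage_states],
            dtype=np.int64,
        )

    def voltage_indices(self) -> np.ndarray:
        return np.array(
            [self.state_names.index(v) for v in self.voltage_states], dtype=np.int64
        )

    def initial_state(self) -> np.ndarray:
        return self._default_state.copy()

    # --- integration ----------------------------------------------------------
    def integrate(
        self,
        duration_ms: float,
        dt: float = 0.01,
        record_dt: float = 0.1,
        protocol: TemperatureProtocol | None = None,
        q10: Q10Settings | None = None,
        y0: np.ndarray | None = None,
        param_overrides: Mapping[str, float] | None = None,
    ) -> SimulationResult:
        if not dt > 0:
            raise ValueError("dt must be positive")
        if duration_ms < dt:
            raise ValueError("duration must be at least one step")
        rec_every = max(1, int(round(record_dt / dt)))
        n_steps = int(round(duration_ms / dt))
        protocol = protocol or TemperatureProtocol(mode="off")
        if q10 is None and protocol.mode != "off":
            q10 = Q10Settings(T0=protocol.T0)
        q, capmask, gamma = self.thermal_vectors(q10)
        y0 = self.initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()
        self._check_state(y0)
        p = self.param_vector(param_overrides)
        code, dT_ss, t_on, t_off, tau, st, sv = protocol.encode()
        status, step, out_t, out_y, gmin, gmax, yf = self._integrator(
            y0, p, q, capmask, gamma,
            code, dT_ss, t_on, t_off, tau, st, sv,
            dt, n_steps, rec_every, self.voltage_indices(), self.gate_indices(),
        )
        if status == 1:
            raise IntegrationError(
                f"{self.name}: gating variable left [0,1] beyond tolerance at step {step}")
        if status == 2:
            raise IntegrationError(
                f"{self.name}: voltage blow-up (|V| > {VOLTAGE_BLOWUP_MV} mV) at step {step}")
        return SimulationResult(self, out_t, out_y, gmin, gmax, yf, protocol)

    def rest(self, settle_ms: float = 2000.0, dt: float = 0.01) -> np.ndarray:
        """State after pre-integrating with zero injected current.

        Removes transient-dependent bias before every experiment; for
        intrinsically silent parameterizations this converges to the resting
        fixed point.
        """
        overrides = {k: 0.0 for k in self.param_names if k in self._injection_params()}
        res = self.integrate(settle_ms, dt=dt, record_dt=1.0, param_overrides=overrides)
        return res.final_state

    def _injection_params(self) -> tuple:
        return ("Iinj",)
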