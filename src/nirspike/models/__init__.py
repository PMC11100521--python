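"""Conductance-based neuron models (HH, CGC shoulder-type, two-compartment N3t)."""

from .base import ConductanceModel, IntegrationError, SimulationResult
from .cgc import CGC
from .hh import HodgkinHuxley
from .n3t import N3t

MODELS = {"hh": HodgkinHuxley, "cgc": CGC, "n3t": N3t}


def get_model(name: str, params=None) -> ConductanceModel:
    """Instantiate a model by name (``"hh"``, ``"cgc"`` or ``"n3t"``)."""
    try:
        cls = MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None
    return cls(params)


__all__ = ["ConductanceModel", "SimulationResult", "IntegrationError",
           "HodgkinHuxley", "CGC", "N3t", "MODELS", "get_model"]
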