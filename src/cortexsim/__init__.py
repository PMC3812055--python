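"""cortexsim: interconnected cortical networks with delayed long-range projections.

A simulator for two Izhikevich spiking networks coupled by delayed
long-range projections (with short-term synaptic depression and simulated
tACS) together with the analysis pipeline that classifies the emergent
macroscopic states (rapid fire / slow propagating / spiral wave) and
quantifies transitions, spectra and cross-correlations.
"""

from . import model_core, topology, state_analysis, signal_analysis, fixtures

__version__ = "0.1.0"

__all__ = [
    "model_core",
    "topology",
    "engine",
    "state_analysis",
    "signal_analysis",
    "experiments",
    "fixtures",
]


def __getattr__(name):
    # engine/experiments import numba; keep them lazy so light-weight use
    # (parameter sampling, analysis of saved records) avoids JIT start-up.
    if name in ("engine", "experiments"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
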