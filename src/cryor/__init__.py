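"""cryor: analysis toolkit for cryorhodopsin spectroscopy and sequences.

Subpackages cover synthetic data generation from packaged scenarios
(`synthgen`), BR-anchored motif mining (`motifs`), photocycle kinetics
and time-resolved fitting (`kinetics`), coherent-oscillation Fourier
analysis (`oscillations`), steady-state titration and photoswitch
models (`photosteady`), patch-clamp charge analysis (`ephys`) and
plain-text I/O (`io`).
"""

__version__ = "0.1.0"

from . import datatypes  # noqa: F401  (import order: io needs __version__)

__all__ = ["__version__", "datatypes", "synthgen", "motifs", "kinetics",
           "oscillations", "photosteady", "ephys", "io"]


def __getattr__(name):
    if name in __all__:
        import importlib
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module 'cryor' has no attribute {name!r}")
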