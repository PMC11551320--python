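"""Conformational-landscape inference for fold-switching proteins from NMR.

The package chains four experimental observables into one kinetic picture of
a fold-switching protein such as KaiB:

* real-time HSQC peak-intensity series after a temperature jump
  (hour-timescale Ground <-> Fold-switched interconversion),
* CEST saturation profiles (millisecond-to-second exchange with sparsely
  populated states),
* constant-time CPMG relaxation dispersion (exchange-regime classification),
* peak-volume tables (direct state populations),

and assembles the fitted rates and populations into a per-temperature free
energy landscape via Boltzmann inversion and the Eyring equation.
"""

import importlib

__version__ = "0.1.0"

_SUBMODULES = (
    "exchange_core",
    "synthetic_data",
    "realtime_kinetics",
    "cest_fitting",
    "cpmg_analysis",
    "landscape",
    "shift_compare",
    "pipeline_io",
)


def __getattr__(name):
    if name in _SUBMODULES:
        return importlib.import_module(f"foldswitch.{name}")
    raise AttributeError(f"module 'foldswitch' has no attribute {name!r}")

__all__ = [
    "exchange_core",
    "synthetic_data",
    "realtime_kinetics",
    "cest_fitting",
    "cpmg_analysis",
    "landscape",
    "shift_compare",
    "pipeline_io",
    "__version__",
]
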