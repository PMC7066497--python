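"""Reference parameter sets for the three oscillatory regimes.

Each preset shares the same external drive and sigmoid/time-constant
defaults and differs only in a handful of connection weights:

* ``healthy`` — gamma-band limit cycle (~44 Hz), the pro-kinetic regime;
* ``tremor``  — ~4 Hz tremor-band oscillation, obtained from the healthy
  set by strengthening corticothalamic feedback (w2), weakening the
  cerebellar drive to the thalamus (w4) and the STN->GPe coupling (w7);
* ``beta``    — ~20 Hz beta-band oscillation, obtained from the tremor set
  by lowering w2 back and raising w4.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .model import ModelParameters

#                w1  w2  w3  w4  w5  w6  w7  w8  w9 w10 w11   ext
_PRESET_TABLE = {
    "healthy": ([20, 5, 8, 25, 15, 5, 19, 5, 15, 20, 20], 3.42),
    "tremor":  ([20, 12, 8, 9, 15, 5, 5, 5, 15, 20, 20], 3.42),
    "beta":    ([20, 5, 8, 20, 15, 5, 5, 5, 15, 20, 20], 3.42),
}

PRESET_NAMES = tuple(_PRESET_TABLE)


def load_preset(name: str) -> ModelParameters:
    """Return the named reference parameter set.

    Raises
    ------
    ConfigurationError
        For unknown names, listing the valid presets.
    """
    try:
        weights, ext = _PRESET_TABLE[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return ModelParameters(weights=weights, ext=ext)
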