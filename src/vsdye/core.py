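"""Shared domain primitives: electronic state labels, voltage conditions, constants.

The membrane normal is the +z axis throughout the package; the bilayer midplane
sits at z = 0 and the dye-bearing leaflet occupies z > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

#: Planck constant x speed of light x Avogadro number, in kcal*nm/mol
#: (thermochemical kcal). Documented to 6 significant figures; converts a
#: molar transition energy E (kcal/mol) to a wavelength hc/E (nm).
HC_KCAL_NM_PER_MOL = 2.85916e4


class State(str, Enum):
    """Electronic state of the chromophore."""

    GROUND = "ground"
    EXCITED = "excited"


@dataclass(frozen=True)
class VoltageCondition:
    """One simulated condition: applied membrane potential and electronic state.

    Parameters
    ----------
    v_mp : float
        Applied transmembrane potential, mV.
    state : State
        ``State.GROUND`` or ``State.EXCITED``.
    """

    v_mp: float
    state: State

    def __post_init__(self) -> None:
        if not math.isfinite(self.v_mp):
            raise ValueError(f"v_mp must be finite, got {self.v_mp!r}")
        object.__setattr__(self, "state", State(self.state))
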