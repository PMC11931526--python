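"""Internal unit system and conversion helpers.

All quantities inside the package are carried in a fixed unit system:
length nm, time ps, mass amu, energy eV. Readers convert on ingestion via a
:class:`UnitMap`; nothing downstream ever needs to know the file units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

#: 1 amu·nm²/ps² expressed in eV (CODATA amu and elementary charge).
KE_AMU_NM2_PS2_TO_EV = 0.0103642688

#: Known length units expressed in nm.
LENGTH_TO_NM = {
    "nm": 1.0,
    "angstrom": 0.1,
    "A": 0.1,
    "bohr": 0.0529177210903,
}

#: Known time units expressed in ps.
TIME_TO_PS = {
    "ps": 1.0,
    "fs": 1e-3,
    "ns": 1e3,
}


@dataclass(frozen=True)
class UnitMap:
    """Declared units of an input file; velocity is length/time."""

    length: str = "nm"
    time: str = "ps"

    @property
    def length_to_nm(self) -> float:
        try:
            return LENGTH_TO_NM[self.length]
        except KeyError:
            raise ValueError(f"unknown length unit {self.length!r}") from None

    @property
    def time_to_ps(self) -> float:
        try:
            return TIME_TO_PS[self.time]
        except KeyError:
            raise ValueError(f"unknown time unit {self.time!r}") from None

    @property
    def velocity_to_nm_ps(self) -> float:
        return self.length_to_nm / self.time_to_ps


def _load_masses() -> dict[str, float]:
    text = resources.files("ejecta.data").joinpath("atomic_masses.json").read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


#: Standard atomic masses (amu), keyed by element symbol.
ATOMIC_MASSES: dict[str, float] = _load_masses()


def atomic_mass(element: str) -> float:
    """Standard atomic mass of ``element`` in amu.

    Raises ``KeyError`` with a readable message for undeclared symbols.
    """
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(
            f"element {element!r} has no declared standard atomic mass"
        ) from None
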