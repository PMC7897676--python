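"""Bundled isotopic constants.

Masses and abundances ship with the package as a versioned TSV so that every
mass printed by this library is reproducible independent of any external
library's tables. Electron mass from CODATA 2018.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

ELECTRON_MASS = 0.000548579909065  # Da, CODATA 2018
PROTON_MASS = 1.00782503224 - ELECTRON_MASS  # 1H minus one electron

_ABUNDANCE_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Isotope:
    mass_number: int
    mass: float  # Da
    abundance: float  # mole fraction


class AtomicMassTable:
    """Per-element isotope lists (mass, abundance), plus the electron mass.

    Isotopes are stored sorted by mass; the lightest stable isotope of each
    element defines its monoisotopic mass.
    """

    def __init__(self, isotopes: dict[str, list[Isotope]],
                 electron_mass: float = ELECTRON_MASS):
        for element, isos in isotopes.items():
            if not isos:
                raise ValueError(f"element {element!r} has no isotopes")
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > _ABUNDANCE_SUM_TOL:
                raise ValueError(
                    f"abundances for {element!r} sum to {total}, not 1")
            if any(i.mass <= 0 for i in isos):
                raise ValueError(f"non-positive isotope mass for {element!r}")
        self._isotopes = {
            el: sorted(isos, key=lambda i: i.mass)
            for el, isos in isotopes.items()
        }
        self.electron_mass = electron_mass

    def __contains__(self, element: str) -> bool:
        return element in self._isotopes

    @property
    def elements(self) -> list[str]:
        return sorted(self._isotopes)

    def isotopes(self, element: str) -> list[Isotope]:
        try:
            return self._isotopes[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} is not in the atomic mass table"
            ) from None

    def monoisotopic_mass(self, element: str) -> float:
        return self.isotopes(element)[0].mass


def _load_bundled() -> AtomicMassTable:
    text = (importlib.resources.files("isoformid.data")
            .joinpath("atomic_masses.tsv").read_text())
    isotopes: dict[str, list[Isotope]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, mass_number, mass, abundance = line.split("\t")
        isotopes.setdefault(element, []).append(
            Isotope(int(mass_number), float(mass), float(abundance)))
    return AtomicMassTable(isotopes)


_DEFAULT: AtomicMassTable | None = None


def default_mass_table() -> AtomicMassTable:
    """The bundled table, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_bundled()
    return _DEFAULT
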