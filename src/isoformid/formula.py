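"""Elemental formulas: parsing, algebra, and exact (monoisotopic) mass.

The :class:`ElementalFormula` is the unit every downstream mass computation is
built on. Masses are computed from the bundled isotope table; protonated
cations (MH+) subtract one electron mass by default, which is what reproduces
Orbitrap-style theoretical m/z values to four decimals (C18H28NO+ gives
274.2165, not 274.2171).
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass

from .constants import AtomicMassTable, default_mass_table
from .errors import (ConfigurationError, DomainError, FormulaParseError,
                     InfeasibleTransformationError)

#: Element set accepted by default; covers every species in the 3-MeO-PCP and
#: MMC case data. Extensible via the ``allowed`` argument of `parse_formula`.
DEFAULT_ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O"})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """Immutable element → count mapping with elementwise algebra.

    Equality is count-map equality; zero counts are dropped. The canonical
    text form follows Hill order (C, H, then alphabetical; fully alphabetical
    when no carbon is present).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for element, n in source.items():
                merged[element] = merged.get(element, 0) + int(n)
        for element, n in merged.items():
            if n < 0:
                raise InfeasibleTransformationError(
                    f"negative count for {element}: {n}")
        self._counts = {el: n for el, n in sorted(merged.items()) if n > 0}
        self._hash = hash(tuple(self._counts.items()))

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element) -> bool:
        return element in self._counts

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise InfeasibleTransformationError(
                    f"cannot remove {other.hill()} from {self.hill()}: "
                    f"{el} count would be {counts[el]}")
        return ElementalFormula(counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    @property
    def n_atoms(self) -> int:
        return sum(self._counts.values())

    def hill(self) -> str:
        """Canonical Hill-order formula text."""
        parts = []
        order: list[str]
        if "C" in self._counts:
            order = ["C"] + (["H"] if "H" in self._counts else [])
            order += sorted(el for el in self._counts if el not in ("C", "H"))
        else:
            order = sorted(self._counts)
        for el in order:
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


@dataclass(frozen=True)
class IonSpecies:
    """An ionic species: the ion's full formula (protons included) + charge.

    For MH+ the ion formula equals the neutral formula plus one H. With
    ``electron_correction`` on (the default) the mass of ``charge`` electrons
    is subtracted, as appropriate for cations.
    """

    formula: ElementalFormula
    charge: int = 1
    electron_correction: bool = True

    def __post_init__(self):
        if self.charge == 0:
            raise DomainError("ionic species require charge != 0")


def parse_formula(text: str,
                  allowed: frozenset[str] | None = DEFAULT_ALLOWED_ELEMENTS,
                  ) -> ElementalFormula:
    """Parse formula text like ``"C18H28NO"`` (counts default to 1).

    ``allowed`` restricts the element vocabulary (``None`` disables the
    check); the default CHNO set catches symbol typos in routine use.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    table = default_mass_table()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaParseError(
                f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in table:
            raise FormulaParseError(
                f"unknown element symbol {element!r} in {text!r}")
        if allowed is not None and element not in allowed:
            raise FormulaParseError(
                f"element {element!r} is outside the allowed set "
                f"{sorted(allowed)}; pass allowed=None or extend the set")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaParseError(
                f"zero count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


def add_formula(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    return a + b


def subtract_formula(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    return a - b


def protonate(neutral: ElementalFormula) -> IonSpecies:
    """The MH+ species of a neutral molecule."""
    return IonSpecies(neutral + ElementalFormula(H=1), charge=1)


def exact_mass(ion: IonSpecies | ElementalFormula,
               table: AtomicMassTable | None = None,
               decimals: int | None = None) -> float:
    """Monoisotopic mass (neutral formula) or m/z (ion species).

    Every atom contributes its lightest-isotope exact mass; for ions the
    electron mass is subtracted per unit positive charge (when
    ``electron_correction`` is set) and the result divided by |charge|.
    ``decimals`` applies round-half-even display rounding; internal
    computation is always full precision.
    """
    table = table or default_mass_table()
    if isinstance(ion, ElementalFormula):
        formula, charge, correct = ion, 0, False
    else:
        formula, charge, correct = ion.formula, ion.charge, ion.electron_correction
    mass = 0.0
    for element, n in formula.items():
        if element not in table:
            raise ConfigurationError(
                f"element {element!r} missing from the atomic mass table")
        mass += n * table.monoisotopic_mass(element)
    if charge != 0:
        if correct:
            mass -= charge * table.electron_mass
        mass /= abs(charge)
    return round(mass, decimals) if decimals is not None else mass


def ppm_error(accurate: float, exact: float,
              decimals: int | None = None) -> float:
    """Signed mass accuracy Δm = (accurate − exact) / exact × 1e6, in ppm."""
    if exact <= 0:
        raise DomainError(f"exact mass must be positive, got {exact}")
    value = (accurate - exact) / exact * 1e6
    return round(value, decimals) if decimals is not None else value


def rdbe(neutral: ElementalFormula) -> float:
    """Ring-and-double-bond equivalents of a neutral formula.

    General valence form 1 + Σ n_i (v_i − 2)/2; for CHNO this reduces to
    C − H/2 + N/2 + 1.
    """
    valence = {"C": 4, "Si": 4, "N": 3, "P": 3, "O": 2, "S": 2,
               "H": 1, "F": 1, "Cl": 1, "Br": 1, "I": 1, "Na": 1}
    total = 1.0
    for element, n in neutral.items():
        try:
            v = valence[element]
        except KeyError:
            raise DomainError(
                f"no valence defined for element {element!r}") from None
        total += n * (v - 2) / 2.0
    return total
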