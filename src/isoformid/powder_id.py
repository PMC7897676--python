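"""Elemental composition search for an unknown accurate MH+ mass.

Candidate neutral formulas are enumerated exhaustively over per-element count
ranges; a candidate is kept when the theoretical m/z of its protonated ion is
within the ppm window of the observed mass and its ring-and-double-bond
equivalents (RDBE) fall in range. Hits are ranked by absolute mass error,
then (when an experimental isotope pattern is supplied) by absolute RIA
error, then by Hill formula text so ranks are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import default_mass_table
from .errors import DomainError
from .formula import ElementalFormula, exact_mass, ppm_error, protonate, rdbe
from .isotopes import IsotopePattern, isotope_pattern, ria, ria_error


@dataclass(frozen=True)
class CompositionSearchSpace:
    """Count bounds per element plus the ppm window and RDBE filter."""

    element_bounds: dict[str, tuple[int, int]]
    ppm_tolerance: float = 3.0
    rdbe_min: float = 0.0
    rdbe_max: float = 25.0
    apply_rdbe: bool = True

    def __post_init__(self):
        if self.ppm_tolerance <= 0:
            raise DomainError("ppm tolerance must be positive")
        for el, (lo, hi) in self.element_bounds.items():
            if lo < 0 or hi < lo:
                raise DomainError(
                    f"bad count range for {el}: [{lo}, {hi}]")

    @classmethod
    def chno(cls, max_c: int = 30, max_h: int = 60, max_n: int = 3,
             max_o: int = 6, **kw) -> "CompositionSearchSpace":
        return cls({"C": (0, max_c), "H": (0, max_h),
                    "N": (0, max_n), "O": (0, max_o)}, **kw)


@dataclass(frozen=True)
class CompositionHit:
    neutral: ElementalFormula
    mh_mz: float
    delta_ppm: float
    rdbe: float
    ria_fit_error_pct: float | None
    rank: int


def search_compositions(observed_mz: float,
                        space: CompositionSearchSpace,
                        experimental_pattern: IsotopePattern | None = None,
                        ) -> list[CompositionHit]:
    """All neutral formulas whose MH+ m/z lies within the ppm window.

    Enumeration is exhaustive over the count lattice with mass-bound pruning
    (depth-first over elements ordered heavy-to-light), so results are
    identical to a naive scan of the full lattice.
    """
    if observed_mz <= 0:
        raise DomainError("observed m/z must be positive")
    table = default_mass_table()
    tol = space.ppm_tolerance
    # target neutral monoisotopic mass window
    proton = table.monoisotopic_mass("H") - table.electron_mass
    lo_mass = observed_mz * (1 - tol * 1e-6) - proton
    hi_mass = observed_mz * (1 + tol * 1e-6) - proton

    elements = sorted(space.element_bounds,
                      key=lambda el: -table.monoisotopic_mass(el))
    masses = [table.monoisotopic_mass(el) for el in elements]
    bounds = [space.element_bounds[el] for el in elements]
    # minimal achievable remaining mass per suffix (counts at their minimum)
    min_suffix = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        min_suffix[i] = min_suffix[i + 1] + bounds[i][0] * masses[i]

    exp_ria = ria(experimental_pattern) if experimental_pattern is not None else None
    hits: list[tuple] = []

    def descend(i: int, counts: list[int], mass: float):
        if mass + min_suffix[i] > hi_mass:
            return
        if i == len(elements):
            if mass < lo_mass:
                return
            neutral = ElementalFormula(dict(zip(elements, counts)))
            if not neutral:
                return
            if space.apply_rdbe:
                r = rdbe(neutral)
                if not space.rdbe_min <= r <= space.rdbe_max:
                    return
            else:
                r = rdbe(neutral)
            ion = protonate(neutral)
            mz = exact_mass(ion, table)
            dm = ppm_error(observed_mz, mz)
            if abs(dm) > tol:
                return
            fit = None
            if exp_ria is not None:
                fit = ria_error(exp_ria, ria(isotope_pattern(ion, 2, table)))
            hits.append((neutral, mz, dm, r, fit))
            return
        lo, hi = bounds[i]
        m = masses[i]
        for n in range(lo, hi + 1):
            new_mass = mass + n * m
            if new_mass + min_suffix[i + 1] > hi_mass:
                break
            descend(i + 1, counts + [n], new_mass)

    descend(0, [], 0.0)

    def sort_key(h):
        neutral, mz, dm, r, fit = h
        return (abs(dm), abs(fit) if fit is not None else 0.0, neutral.hill())

    hits.sort(key=sort_key)
    return [CompositionHit(neutral, mz, dm, r, fit, rank)
            for rank, (neutral, mz, dm, r, fit) in enumerate(hits, start=1)]
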