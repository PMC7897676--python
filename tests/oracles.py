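"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they check:
isotope patterns are obtained by exhaustive per-atom enumeration (small
formulas) or by direct polynomial convolution of single-atom shift
distributions (large formulas), and the composition search by a naive scan
of the full count lattice.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np

from isoformid.constants import default_mass_table
from isoformid.formula import ElementalFormula


def brute_force_pattern(formula: ElementalFormula, charge: int = 1,
                        electron_correction: bool = True,
                        max_shift: int = 3):
    """Exhaustive enumeration over every per-atom isotope assignment.

    Feasible only for ~10 atoms. Returns {shift: (abundance_rel_M0,
    mz_of_most_probable_isotopologue)}; labeled atom assignments are grouped
    into isotopologues (per-element isotope count vectors) before taking the
    most probable one, matching what a mass spectrometer resolves.
    """
    table = default_mass_table()
    atoms = []
    for element, n in formula.items():
        atoms.extend([table.isotopes(element)] * n)
    light_mass = sum(isos[0].mass for isos in atoms)
    light_nominal = sum(isos[0].mass_number for isos in atoms)
    iso_groups = defaultdict(float)  # isotopologue signature -> probability
    for combo in itertools.product(*[range(len(isos)) for isos in atoms]):
        prob = 1.0
        mass = 0.0
        nominal = 0
        signature = defaultdict(int)
        for choice, isos in zip(combo, atoms):
            iso = isos[choice]
            prob *= iso.abundance
            mass += iso.mass
            nominal += iso.mass_number
            signature[(isos[0].mass_number, iso.mass_number)] += 1
        shift = nominal - light_nominal
        if shift > max_shift:
            continue
        key = (shift, round(mass, 9), tuple(sorted(signature.items())))
        iso_groups[key] += prob
    bins: dict[int, list] = {}
    for (shift, mass, _sig), prob in iso_groups.items():
        entry = bins.setdefault(shift, [0.0, 0.0, 0.0])  # total, best, mass
        entry[0] += prob
        if prob > entry[1]:
            entry[1], entry[2] = prob, mass
    base = bins[0][0]
    electron = table.electron_mass if electron_correction else 0.0
    out = {}
    for shift, (total, _best, mass) in sorted(bins.items()):
        mz = (mass - charge * electron) / abs(charge) if charge else mass
        out[shift] = (total / base, mz)
    return out


def convolution_abundances(formula: ElementalFormula,
                           max_shift: int = 3) -> np.ndarray:
    """Bin abundances via repeated polynomial convolution, relative to M+0.

    One polynomial per atom in the nominal-shift variable; exact after
    truncation at max_shift, like the analytic route but algorithmically
    disjoint from the multinomial enumeration.
    """
    table = default_mass_table()
    poly = np.zeros(max_shift + 1)
    poly[0] = 1.0
    for element, n in formula.items():
        isos = table.isotopes(element)
        single = np.zeros(max_shift + 1)
        for iso in isos:
            shift = iso.mass_number - isos[0].mass_number
            if shift <= max_shift:
                single[shift] += iso.abundance
        for _ in range(n):
            poly = np.convolve(poly, single)[:max_shift + 1]
    return poly / poly[0]


def brute_force_composition_search(observed_mz: float,
                                   bounds: dict[str, tuple[int, int]],
                                   ppm_tolerance: float,
                                   rdbe_range=(0.0, 25.0)):
    """Naive scan of the full lattice; returns neutral Hill strings."""
    from isoformid.formula import exact_mass, ppm_error, protonate, rdbe
    elements = sorted(bounds)
    hits = []
    ranges = [range(bounds[el][0], bounds[el][1] + 1) for el in elements]
    for counts in itertools.product(*ranges):
        if sum(counts) == 0:
            continue
        neutral = ElementalFormula(dict(zip(elements, counts)))
        r = rdbe(neutral)
        if not rdbe_range[0] <= r <= rdbe_range[1]:
            continue
        mz = exact_mass(protonate(neutral))
        if abs(ppm_error(observed_mz, mz)) <= ppm_tolerance:
            hits.append(neutral.hill())
    return sorted(hits)
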