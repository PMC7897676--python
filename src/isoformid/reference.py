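"""Literature-reported LC-HRMS reference data for 3-MeO-PCP and metabolites.

These are the published chromatographic and mass-spectrometric values for
3-methoxyphencyclidine (3-MeO-PCP, neutral C18H27NO) and its phase I / phase
II metabolites identified in human blood and urine: MH+ elemental
composition, retention time(s), the exact/accurate mass and mass-accuracy
(Δm, ppm) triple for each isotopic peak M+0..M+3, and the observed
collision-induced product ions. They serve as regression targets for the mass
engine, as the transformation-rule closure check, and as the planting list
for the synthetic biofluid generator.

Missing entries (weak metabolites whose higher isotopic peaks or fragments
were not observed) are ``None``; for isomer groups the starred retention time
marks the most abundant isomer, whose MS data the row refers to.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formula import ElementalFormula, parse_formula

PARENT_ACRONYM = "3-MeO-PCP"
PARENT_NEUTRAL = parse_formula("C18H27NO")
PARENT_RT_MIN = 7.74

#: The screening panel observed to cover the seven most abundant urinary
#: analytes: the parent plus the main phase I and phase II metabolites.
URINE_PANEL_ACRONYMS = ("3-MeO-PCP", "M1a", "M1b", "M1g", "M1h", "M2a", "M2c")


@dataclass(frozen=True)
class IsotopePeakRecord:
    exact: float
    accurate: float
    delta_ppm: float


@dataclass(frozen=True)
class MetaboliteRecord:
    name: str
    acronym: str
    mh_composition: str          # MH+ ion formula, Hill order
    rt_min: tuple[float, ...]    # all isomer retention times
    rt_star: int                 # index of the most abundant isomer
    peaks: tuple[IsotopePeakRecord | None, ...]  # M+0..M+3
    product_ions: tuple[float, ...]
    phase: str                   # "parent", "I" or "II"
    artifact: bool = False

    @property
    def mh_formula(self) -> ElementalFormula:
        return parse_formula(self.mh_composition)

    @property
    def neutral_formula(self) -> ElementalFormula:
        return self.mh_formula - ElementalFormula(H=1)

    @property
    def primary_rt(self) -> float:
        return self.rt_min[self.rt_star]


def _rec(name, acronym, comp, rts, star, cells, ions, phase, artifact=False):
    peaks = tuple(
        None if c is None else IsotopePeakRecord(*c) for c in cells)
    return MetaboliteRecord(name, acronym, comp, tuple(rts), star, peaks,
                            tuple(ions), phase, artifact)


REFERENCE_TABLE: tuple[MetaboliteRecord, ...] = (
    _rec("3-MeO-PCP", "3-MeO-PCP", "C18H28NO", [7.74], 0,
         [(274.2165, 274.2164, -0.36), (275.2199, 275.2198, -0.36),
          (276.2233, 276.2231, -0.72), (277.2266, 277.2266, 0.0)],
         [189.1272, 121.0647, 95.0492, 91.0543, 86.0965, 81.0700], "parent"),
    _rec("O-demethyl-", "M1a", "C17H26NO", [6.42], 0,
         [(260.2009, 260.2008, -0.38), (261.2042, 261.2041, -0.38),
          (262.2076, 262.2074, -0.76), (263.2110, 263.2109, -0.38)],
         [175.1115, 107.0491, 95.0492, 91.0542, 86.0965, 81.0700, 79.0544], "I"),
    _rec("O-demethyl-piperidine-OH-", "M1b", "C17H26NO2", [5.49], 0,
         [(276.1958, 276.1956, -0.72), (277.1992, 277.1990, -0.72),
          (278.2025, 278.2023, -0.72), (279.2059, 279.2061, 0.72)],
         [175.1113, 107.0490, 102.0912, 95.0491, 84.0808, 81.0699, 77.0388], "I"),
    _rec("O-demethyl-cyclohexyl-HO-", "M1c", "C17H26NO2",
         [4.55, 5.01, 5.09], 1,
         [(276.1958, 276.1958, 0.0), (277.1992, 277.1992, 0.0),
          (278.2025, 278.2025, 0.0), (279.2059, 279.2057, -0.72)],
         [173.0959, 107.0491, 86.0966, 79.0544, 77.0387], "I"),
    _rec("O-demethyl-cyclohexyl-HO-dehydro-oxo-piperidine-", "M1d",
         "C17H22NO3", [5.30], 0,
         [(288.1594, 288.1592, -0.69), (289.1628, 289.1625, -1.04),
          (290.1661, 290.1653, -2.76), None],
         [98.0601], "I"),
    _rec("Piperidine-HO-", "M1e", "C18H28NO2", [6.68], 0,
         [(290.2115, 290.2112, -1.03), (291.2148, 291.2146, -0.69),
          (292.2182, 292.2180, -0.68), (293.2215, 293.2211, -1.36)],
         [189.1274, 121.0648, 102.0914, 91.0543, 84.0809, 81.0701], "I"),
    _rec("Cyclohexyl-HO- isomers", "M1f", "C18H28NO2",
         [5.62, 6.18, 6.34], 0,
         [(290.2115, 290.2112, -1.03), (291.2148, 291.2146, -0.69),
          (292.2182, 292.2179, -1.03), (293.2215, 293.2211, -1.36)],
         [205.1221, 187.1116, 121.0647, 91.0543, 86.0965, 79.0544, 77.0387], "I"),
    _rec("O-demethyl-piperidine-di-HO-", "M1g", "C17H26NO3", [5.88], 0,
         [(292.1907, 292.1903, -1.37), (293.1941, 293.1938, -1.02),
          (294.1974, 294.1971, -1.02), (295.1983, 295.1977, -2.03)],
         [175.1114, 118.0860, 107.0490, 101.0597, 81.0699, 79.0544, 77.0387], "I"),
    _rec("Piperidine-di-HO-", "M1h", "C18H28NO3", [6.95], 0,
         [(306.2064, 306.2061, -0.98), (307.2097, 307.2094, -0.98),
          (308.2131, 308.2129, -0.65), (309.2140, 309.2136, -1.29)],
         [189.1270, 121.0646, 118.0861, 101.0597, 100.0757, 91.0543, 81.0700], "I"),
    _rec("Cyclohexyl-HO-piperidine-HO- isomers", "M1i", "C18H28NO3",
         [4.45, 5.15, 5.33], 0,
         [(306.2064, 306.2063, -0.33), (307.2097, 307.2096, -0.33),
          (308.2131, 308.2131, 0.0), (309.2140, 309.2127, -4.20)],
         [187.1114, 121.0647, 102.0914, 84.0808], "I"),
    _rec("O-demethyl-cyclohexyl-HO-piperidine-di-HO-", "M1k",
         "C17H26NO4", [4.72], 0,
         [(308.1856, 308.1856, 0.0), (309.1890, 309.1889, -0.32),
          (310.1923, 310.1921, -0.64), None],
         [191.1064, 173.0958, 118.0861, 101.0597], "I"),
    _rec("Carboxy- methyl artifact", "M1m", "C19H30NO3", [7.86], 0,
         [(320.2220, 320.2217, -0.94), (321.2254, 321.2251, -0.93),
          (322.2287, 322.2285, -0.62), (323.2296, 323.2297, 0.31)],
         [189.1271, 132.1017, 115.0753], "I", artifact=True),
    _rec("O-(demethyl-carboxy-cyclohexyl-HO-) methyl artifact", "M1n",
         "C18H28NO4", [5.73], 0,
         [(322.2013, 322.2010, -0.93), (323.2046, 323.2044, -0.62),
          (324.2080, 324.2075, -1.54), None],
         [], "I", artifact=True),
    _rec("Cyclohexyl-OH-piperidine-di-OH-", "M1o", "C18H28NO4", [5.04], 0,
         [(322.2013, 322.2012, -0.31), (323.2046, 323.2045, -0.31),
          (324.2080, 324.2081, 0.31), (325.2089, 325.2079, -3.07)],
         [187.1115, 118.0860, 100.0756], "I"),
    _rec("Carboxy-cyclohexyl-HO- methyl artifact isomers", "M1p",
         "C19H30NO4", [7.52, 7.69, 8.23], 1,
         [(336.2169, 336.2166, -0.89), (337.2203, 337.2199, -1.19),
          (338.2236, 338.2230, -1.77), None],
         [], "I", artifact=True),
    _rec("O-demethyl- glucuronide", "M2a", "C23H34NO7", [4.47], 0,
         [(436.2330, 436.2326, -0.92), (437.2363, 437.2359, -0.91),
          (438.2397, 438.2398, 0.23), (439.2406, 439.2398, -1.82)],
         [175.1114, 107.0490, 95.0128, 86.0964, 81.0700, 79.0544], "II"),
    _rec("O-demethyl-aryl-OH glucuronide", "M2b", "C23H34NO8", [3.41], 0,
         [(452.2279, 452.2274, -1.11), (453.2312, 453.2310, -0.44),
          (454.2346, 454.2346, 0.0), (455.2355, 455.2344, -2.42)],
         [191.1063, 173.0958, 107.0490, 86.0964, 79.0543], "II"),
    _rec("O-demethyl-piperidine-OH- glucuronide", "M2c", "C23H34NO8",
         [4.07], 0,
         [(452.2279, 452.2275, -0.88), (453.2312, 453.2310, -0.44),
          (454.2346, 454.2346, 0.0), (455.2355, 455.2346, -1.98)],
         [175.1114, 107.0490, 102.0913, 84.0808, 81.0699], "II"),
    _rec("O-demethyl-aryl-OH-dihydropyridine-OH- glucuronide", "M2d",
         "C23H30NO9", [4.20], 0,
         [(464.1915, 464.1914, -0.22), (465.1949, 465.1947, -0.43),
          (466.1982, 466.1982, 0.0), (467.1991, 467.1987, -0.86)],
         [173.0958, 98.0601, 79.0545], "II"),
    _rec("Piperidine-OH glucuronide", "M2e", "C24H36NO8", [5.54], 0,
         [(466.2435, 466.2429, -1.29), (467.2469, 467.2465, -0.86),
          (468.2503, 468.2501, -0.43), (469.2511, 469.2501, -2.13)],
         [278.1227, 189.1270, 121.0646, 102.0913, 85.0284, 84.0808, 81.0700],
         "II"),
    _rec("O-demethyl-cyclohexyl-HO-piperidine-HO- glucuronide", "M2f",
         "C23H34NO9", [3.77], 0,
         [(468.2228, 468.2226, -0.43), (469.2262, 469.2258, -0.85),
          (470.2295, 470.2294, -0.21), (471.2304, 471.2298, -1.27)],
         [], "II"),
    _rec("O-demethyl-piperidine-di-OH- glucuronide", "M2g", "C23H34NO9",
         [4.44], 0,
         [(468.2228, 468.2225, -0.64), (469.2262, 469.2259, -0.64),
          (470.2295, 470.2293, -0.43), (471.2304, 471.2295, -1.91)],
         [145.0657, 107.0490, 84.0808, 79.0543], "II"),
    _rec("Cyclohexyl-HO-piperidine-HO- glucuronide", "M2h", "C24H36NO9",
         [4.53], 0,
         [(482.2385, 482.2382, -0.62), (483.2418, 483.2416, -0.41),
          (484.2452, 484.2449, -0.62), (485.2461, 485.2465, 0.82)],
         [187.1115, 159.0802, 121.0647, 102.0914, 84.0809], "II"),
    _rec("Piperidine-di-OH- glucuronide", "M2i", "C24H36NO9", [5.93], 0,
         [(482.2385, 482.2379, -1.24), (483.2418, 483.2414, -0.83),
          (484.2452, 484.2449, -0.62), (485.2461, 485.2460, -0.21)],
         [121.0646, 118.0861], "II"),
)


def record(acronym: str) -> MetaboliteRecord:
    for rec in REFERENCE_TABLE:
        if rec.acronym == acronym:
            return rec
    raise KeyError(acronym)


def distinct_mh_compositions() -> set[str]:
    """All distinct MH+ compositions in the reference table (Hill text)."""
    return {r.mh_formula.hill() for r in REFERENCE_TABLE}


#: Relative urinary abundance profile used by the synthetic generator; the
#: panel analytes dominate and all remaining metabolites are minor, matching
#: the reported ion-chromatogram area ordering (elevated metabolite-to-parent
#: ratios for M1h, M1g and M2a; every non-panel metabolite far below).
DEFAULT_URINE_ABUNDANCE: dict[str, float] = {
    "3-MeO-PCP": 100.0,
    "M1h": 130.0, "M1g": 110.0, "M2a": 120.0,
    "M1a": 60.0, "M1b": 45.0, "M2c": 40.0,
    "M1c": 6.0, "M1d": 1.5, "M1e": 8.0, "M1f": 7.0, "M1i": 5.0,
    "M1k": 2.0, "M1m": 4.0, "M1n": 1.0, "M1o": 3.0, "M1p": 2.5,
    "M2b": 5.0, "M2d": 1.2, "M2e": 6.5, "M2f": 1.8, "M2g": 3.5,
    "M2h": 4.5, "M2i": 2.2,
}
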