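"""Ground-truth-tagged synthetic data for every pipeline stage.

The raw case data behind this kind of forensic workflow is never deposited
(police casework), so the pipeline is exercised on synthetic inputs whose
ground truth is known exactly:

* MS1 peak tables emulating the structure of the 3-MeO-PCP biofluid data —
  metabolite MH+ isotope envelopes with ppm-scale mass jitter, earlier
  retention times than the parent, log-normal abundances, decoy peaks;
* solid-deposition IR libraries containing positional-isomer families that
  share most of their absorption bands, with the differing bands (and small
  position shifts of the shared ones) concentrated in the fingerprint region
  below 1500 cm^-1, plus unrelated decoy compounds.

Every generator draws all randomness from one seeded NumPy generator and
records the seed, so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .formula import ElementalFormula, parse_formula, protonate
from .ir import GRID_MAX, GRID_MIN, IRLibrary, IRSpectrum, default_grid
from .isotopes import isotope_pattern
from .metabolites import default_rule_set, enumerate_candidates
from .peaks import COLLISION_ENERGIES, PeakTable
from . import reference

# ---------------------------------------------------------------------------
# MS peak tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedAnalyte:
    """One analyte the generator puts into a peak table."""

    analyte_id: str
    neutral: ElementalFormula
    rt_min: float
    abundance: float
    product_ions: tuple[float, ...] = ()
    path: str = ""


@dataclass(frozen=True)
class MSSimConfig:
    """Study conditions for the synthetic biofluid peak table.

    Defaults mirror the 3-MeO-PCP urine case: parent at 7.74 min, metabolite
    retention times strictly below the parent, sub-ppm mass jitter (the
    observed |Δm| never exceeded ~1.4 ppm at M+0), a few percent of
    relative envelope noise, and a log-normal abundance spread.
    """

    parent_formula: str = "C18H27NO"
    parent_rt: float = reference.PARENT_RT_MIN
    depth: int = 3
    inclusion_probability: float = 1.0
    abundance_mu: float = 3.0        # log-normal log-mean of planted analytes
    abundance_sigma: float = 1.0
    mass_jitter_ppm: float = 1.0
    mass_bias_ppm: float = 0.0
    envelope_noise: float = 0.02     # relative, per isotopic label
    rt_band: tuple[float, float] = (0.4, 0.98)  # fraction of parent tR
    n_labels: int = 4
    decoy_peaks: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.mass_jitter_ppm < 0 or self.envelope_noise < 0:
            raise DomainError("noise levels must be non-negative")
        if not 0 <= self.inclusion_probability <= 1:
            raise DomainError("inclusion probability must be in [0, 1]")


def rule_based_plants(config: MSSimConfig,
                      rng: np.random.Generator) -> list[PlantedAnalyte]:
    """Plants drawn from the transformation-rule candidate set."""
    parent = parse_formula(config.parent_formula)
    lo, hi = config.rt_band
    plants = [PlantedAnalyte("parent", parent, config.parent_rt,
                             float(np.exp(config.abundance_mu
                                          + config.abundance_sigma)),
                             path="parent")]
    for cand in enumerate_candidates(parent, default_rule_set(), config.depth):
        if cand.is_parent:
            continue
        if rng.uniform() > config.inclusion_probability:
            continue
        rt = float(rng.uniform(lo, hi) * config.parent_rt)
        abundance = float(rng.lognormal(config.abundance_mu,
                                        config.abundance_sigma))
        plants.append(PlantedAnalyte(cand.label, cand.neutral, rt, abundance,
                                     path="+".join(cand.path)))
    return plants


def reference_plants(
        abundance_by_acronym: dict[str, float] | None = None,
        minor_isomer_factor: float = 0.4) -> list[PlantedAnalyte]:
    """Plants reproducing the published urinary metabolite panel.

    Every reference metabolite is planted at each of its reported retention
    times; non-starred isomer features get ``minor_isomer_factor`` of the
    acronym's abundance. Abundances default to the reported ion-chromatogram
    area ordering, in which the parent plus M1a, M1b, M1g, M1h, M2a and M2c
    dominate.
    """
    abundances = abundance_by_acronym or reference.DEFAULT_URINE_ABUNDANCE
    plants = []
    for rec in reference.REFERENCE_TABLE:
        base = abundances.get(rec.acronym)
        if base is None:
            continue
        for i, rt in enumerate(rec.rt_min):
            scale = 1.0 if i == rec.rt_star else minor_isomer_factor
            suffix = "" if len(rec.rt_min) == 1 else f"#{i + 1}"
            plants.append(PlantedAnalyte(
                rec.acronym + suffix, rec.neutral_formula, rt,
                base * scale, rec.product_ions, path=rec.name))
    return plants


def simulate_peak_table(config: MSSimConfig,
                        plants: list[PlantedAnalyte] | None = None,
                        ) -> tuple[PeakTable, pd.DataFrame]:
    """Emit a centroided peak table plus its ground-truth bookkeeping.

    Each planted analyte contributes an M+0..M+3 isotope cluster at
    ``pattern m/z x (1 + (bias + N(0, jitter)) x 1e-6)`` with multiplicative
    envelope noise; decoys are single peaks uniform in m/z. The truth table
    lists feature ids against planted formulas, paths and abundances.
    """
    rng = np.random.default_rng(config.seed)
    if plants is None:
        plants = rule_based_plants(config, rng)
    rows = []
    truth_rows = []
    for i, plant in enumerate(plants):
        fid = f"F{i + 1:04d}"
        pattern = isotope_pattern(protonate(plant.neutral), config.n_labels)
        ions = {ce: [] for ce in COLLISION_ENERGIES}
        for j, mz in enumerate(plant.product_ions):
            ions[COLLISION_ENERGIES[j % len(COLLISION_ENERGIES)]].append(mz)
        ion_cols = {
            f"product_ions_{ce}ev": ";".join(f"{v:.4f}" for v in vals)
            for ce, vals in ions.items()}
        for peak in pattern:
            shift = (config.mass_bias_ppm
                     + rng.normal(0.0, config.mass_jitter_ppm)) * 1e-6
            noise = rng.normal(0.0, config.envelope_noise)
            intensity = plant.abundance * peak.abundance * max(0.0, 1.0 + noise)
            rows.append({
                "feature_id": fid,
                "mz": peak.mz * (1.0 + shift),
                "intensity": intensity,
                "rt_min": plant.rt_min,
                **ion_cols,
            })
        truth_rows.append({
            "feature_id": fid,
            "analyte_id": plant.analyte_id,
            "neutral": plant.neutral.hill(),
            "mh_composition": (plant.neutral + ElementalFormula(H=1)).hill(),
            "rt_min": plant.rt_min,
            "abundance": plant.abundance,
            "path": plant.path,
            "seed": config.seed,
        })
    for d in range(config.decoy_peaks):
        rows.append({
            "feature_id": f"D{d + 1:04d}",
            "mz": float(rng.uniform(120.0, 520.0)),
            "intensity": float(rng.lognormal(config.abundance_mu - 2.0, 1.0)),
            "rt_min": float(rng.uniform(0.5, config.parent_rt + 2.0)),
            "product_ions_10ev": "", "product_ions_25ev": "",
            "product_ions_50ev": "",
        })
    table = PeakTable(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)
    return table, truth


def simulate_urine_table(seed: int = 0, mass_jitter_ppm: float = 1.0,
                         decoy_peaks: int = 30,
                         ) -> tuple[PeakTable, pd.DataFrame]:
    """The reference-panel urine scenario at the stated study conditions."""
    config = MSSimConfig(seed=seed, mass_jitter_ppm=mass_jitter_ppm,
                         decoy_peaks=decoy_peaks)
    return simulate_peak_table(config, reference_plants())


# ---------------------------------------------------------------------------
# IR libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IRSimConfig:
    """Study conditions for the synthetic solid-phase IR library.

    Compounds are sums of Gaussian bands on the 650-4000 cm^-1 / 4 cm^-1
    grid; solid-deposition spectra are sharp, hence narrow default widths.
    Positional-isomer families share ``shared_band_fraction`` of their bands
    — but even the shared modes shift by a few wavenumbers between isomers
    (``shared_position_jitter``), and the truly differing bands live in the
    fingerprint region below 1500 cm^-1. Queries add white noise and slow
    baseline drift.
    """

    n_decoys: int = 20
    n_isomer_families: int = 3
    family_size: int = 3
    bands_per_compound: tuple[int, int] = (15, 30)
    band_width: tuple[float, float] = (2.5, 6.0)        # Gaussian sigma, cm^-1
    band_amplitude: tuple[float, float] = (0.2, 1.0)
    shared_band_fraction: float = 0.8
    shared_position_jitter: float = 12.0                # cm^-1
    fingerprint_max: float = 1500.0
    noise_amplitude: float = 0.005
    baseline_drift: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shared_band_fraction <= 1:
            raise DomainError("shared band fraction must be in [0, 1]")
        lo, hi = self.band_width
        if lo <= 0 or hi < lo:
            raise DomainError("bad band width range")


def _band_spectrum(grid, centers, widths, amps) -> np.ndarray:
    out = np.zeros_like(grid)
    for c, w, a in zip(centers, widths, amps):
        out += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return out


def _random_bands(rng, n, lo, hi, config):
    centers = rng.uniform(lo, hi, size=n)
    widths = rng.uniform(*config.band_width, size=n)
    amps = rng.uniform(*config.band_amplitude, size=n)
    return centers, widths, amps


def simulate_ir_library(config: IRSimConfig,
                        ) -> tuple[IRLibrary, list[tuple[IRSpectrum, str]]]:
    """Build a library with isomer families and decoys, plus noisy queries.

    Returns the library and one query per isomer family: the family's first
    member with noise and baseline drift added, labeled with its true name.
    """
    rng = np.random.default_rng(config.seed)
    grid = default_grid()
    lo, hi = GRID_MIN + 30.0, GRID_MAX - 50.0
    library = IRLibrary()
    queries: list[tuple[IRSpectrum, str]] = []

    for d in range(config.n_decoys):
        n = int(rng.integers(*config.bands_per_compound, endpoint=True))
        spec = _band_spectrum(grid, *_random_bands(rng, n, lo, hi, config))
        library.add(IRSpectrum(grid, spec, name=f"decoy{d + 1:02d}"))

    for fam in range(config.n_isomer_families):
        n = int(rng.integers(*config.bands_per_compound, endpoint=True))
        n_shared = int(round(config.shared_band_fraction * n))
        shared = _random_bands(rng, n_shared, lo, hi, config)
        for iso in range(config.family_size):
            # shared modes, perturbed by positional isomerism
            centers = shared[0] + rng.uniform(-config.shared_position_jitter,
                                              config.shared_position_jitter,
                                              size=n_shared)
            signal = _band_spectrum(grid, centers, shared[1], shared[2])
            # isomer-specific bands in the fingerprint region
            own = _random_bands(rng, n - n_shared, lo,
                                config.fingerprint_max, config)
            signal = signal + _band_spectrum(grid, *own)
            name = f"fam{fam + 1}-iso{iso + 1}"
            library.add(IRSpectrum(grid, signal, name=name))
            if iso == 0:
                noise = rng.normal(0.0, config.noise_amplitude, size=len(grid))
                phase = rng.uniform(0, 2 * np.pi)
                drift = config.baseline_drift * np.sin(
                    2 * np.pi * (grid - grid[0]) / (grid[-1] - grid[0])
                    + phase)
                queries.append((IRSpectrum(grid, signal + noise + drift,
                                           name=f"query-{name}"), name))
    return library, queries
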