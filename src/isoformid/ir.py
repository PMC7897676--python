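"""Infrared spectral-library search by first-derivative correlation.

Solid-deposition GC-FTIR spectra have sharp absorption bands, which makes a
first-derivative correlation score very sensitive to band positions — the
property that lets it pull apart positional isomers whose band *sets* largely
overlap but whose positions shift. The quality match factor (QMF) used here
is 100 x max(r, 0), where r is the Pearson correlation between
Savitzky-Golay first derivatives of the two spectra on a common grid. The
derivative estimator (window 9 points, polynomial order 2), the clamping of
anti-correlation to zero, and the percent scaling are configurable
engineering choices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import DomainError

GRID_MIN, GRID_MAX, GRID_STEP = 650.0, 4000.0, 4.0


def default_grid(lo: float = GRID_MIN, hi: float = GRID_MAX,
                 step: float = GRID_STEP) -> np.ndarray:
    """The acquisition grid: 650-4000 cm^-1 at 4 cm^-1 resolution."""
    return np.arange(lo, hi + 0.5 * step, step)


@dataclass(frozen=True)
class IRSpectrum:
    """Absorbance vs wavenumber, with minimal acquisition metadata."""

    wavenumbers: np.ndarray     # cm^-1, strictly ascending
    absorbance: np.ndarray
    name: str = ""
    resolution: float = GRID_STEP   # cm^-1
    n_depositions: int = 1
    degenerate: bool = False        # flat spectrum after normalization

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or ab.shape != wn.shape:
            raise DomainError("wavenumber and absorbance shapes differ")
        if len(wn) >= 2 and np.any(np.diff(wn) <= 0):
            raise DomainError("wavenumber grid must be strictly increasing")
        if self.resolution <= 0:
            raise DomainError("resolution must be positive")

    def __len__(self) -> int:
        return len(self.wavenumbers)


class IRLibrary:
    """Named, unique collection of reference spectra."""

    def __init__(self, spectra: list[IRSpectrum] = ()):
        self._spectra: dict[str, IRSpectrum] = {}
        for s in spectra:
            self.add(s)

    def add(self, spectrum: IRSpectrum) -> None:
        if not spectrum.name:
            raise DomainError("library spectra must be named")
        if spectrum.name in self._spectra:
            raise DomainError(f"duplicate library name {spectrum.name!r}")
        self._spectra[spectrum.name] = spectrum

    def __len__(self) -> int:
        return len(self._spectra)

    def __contains__(self, name: str) -> bool:
        return name in self._spectra

    def __getitem__(self, name: str) -> IRSpectrum:
        return self._spectra[name]

    @property
    def names(self) -> list[str]:
        return sorted(self._spectra)

    def items(self):
        return self._spectra.items()


@dataclass(frozen=True)
class Hit:
    rank: int
    name: str
    qmf: float


class HitList(tuple):
    """Ordered, QMF-descending library search result."""

    def __new__(cls, hits):
        hits = tuple(hits)
        for a, b in zip(hits, hits[1:]):
            if b.qmf > a.qmf + 1e-12:
                raise DomainError("hit list must be QMF non-increasing")
        return super().__new__(cls, hits)

    def top(self) -> Hit:
        return self[0]


def preprocess(spectrum: IRSpectrum, target_grid: np.ndarray | None = None,
               min_overlap: float = 0.90) -> IRSpectrum:
    """Interpolate onto a common grid and min-max normalize to [0, 1].

    Grid points outside the spectrum's range are truncated; the spectrum must
    overlap at least ``min_overlap`` of the target grid. A constant spectrum
    normalizes to all zeros and carries a ``degenerate`` flag.
    """
    grid = default_grid() if target_grid is None else np.asarray(target_grid,
                                                                 dtype=float)
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    inside = (grid >= lo) & (grid <= hi)
    if inside.sum() < min_overlap * len(grid):
        raise DomainError(
            f"spectrum {spectrum.name!r} covers {inside.sum()} of "
            f"{len(grid)} grid points (< {min_overlap:.0%} overlap)")
    sub = grid[inside]
    values = np.interp(sub, spectrum.wavenumbers, spectrum.absorbance)
    span = values.max() - values.min()
    degenerate = span <= 0
    values = np.zeros_like(values) if degenerate else (values - values.min()) / span
    return replace(spectrum, wavenumbers=sub, absorbance=values,
                   degenerate=degenerate)


#: Savitzky-Golay derivative settings: 9-point window, order-2 polynomial.
SG_WINDOW = 9
SG_ORDER = 2


def _derivative(x: np.ndarray) -> np.ndarray:
    return savgol_filter(x, SG_WINDOW, SG_ORDER, deriv=1)


def qmf(query: IRSpectrum, reference: IRSpectrum) -> float:
    """Quality match factor: 100 x max(Pearson r of first derivatives, 0)."""
    if len(query) != len(reference) or not np.allclose(
            query.wavenumbers, reference.wavenumbers):
        raise DomainError("spectra must share one grid; preprocess() first")
    if len(query) < 16:
        raise DomainError("need at least 16 grid points")
    dq, dr = _derivative(query.absorbance), _derivative(reference.absorbance)
    sq, sr = dq.std(), dr.std()
    if sq == 0 or sr == 0:
        return 0.0
    r = float(np.corrcoef(dq, dr)[0, 1])
    return 100.0 * max(r, 0.0)


def rank_library(query: IRSpectrum, library: IRLibrary,
                 target_grid: np.ndarray | None = None) -> HitList:
    """QMF of the query against every library entry, ranked descending.

    Ties break alphabetically by name so ranks are reproducible.
    """
    if len(library) == 0:
        raise DomainError("empty library")
    grid = default_grid() if target_grid is None else target_grid
    q = preprocess(query, grid)
    scored = []
    for name, ref in library.items():
        scored.append((qmf(q, preprocess(ref, grid)), name))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return HitList(Hit(rank, name, score)
                   for rank, (score, name) in enumerate(scored, start=1))


def coadd(depositions: list[IRSpectrum]) -> IRSpectrum:
    """Pointwise sum of consecutive depositions on one disc.

    Deposition physically accumulates analyte, so signal grows ~n while
    independent per-scan noise grows ~sqrt(n) — co-addition, not averaging.
    """
    if not depositions:
        raise DomainError("need at least one deposition")
    first = depositions[0]
    total = np.array(first.absorbance, dtype=float)
    n = first.n_depositions
    for s in depositions[1:]:
        if len(s) != len(first) or not np.allclose(s.wavenumbers,
                                                   first.wavenumbers):
            raise DomainError("all depositions must share one grid")
        total = total + s.absorbance
        n += s.n_depositions
    return replace(first, absorbance=total, n_depositions=n)


@dataclass(frozen=True)
class DepositionSimConfig:
    """Simulated deposition ladder for limit-of-identification studies.

    Each GC run deposits ``amplitude`` x the reference band pattern onto the
    disc; the spectrum measured after n depositions sees n-fold signal, and
    the acquisition integrates proportionally longer so the effective
    per-point noise shrinks as 1/sqrt(n) relative to a single scan of noise
    standard deviation ``noise_sigma`` (on the normalized-reference scale).
    """

    reference: IRSpectrum
    amplitude: float = 0.008
    noise_sigma: float = 0.02
    baseline_drift: float = 0.01
    max_depositions: int = 15
    n_replicates: int = 30
    seed: int = 0

    def measure(self, n: int, rng: np.random.Generator) -> IRSpectrum:
        """One simulated measurement of the disc after n depositions."""
        if n < 1:
            raise DomainError("need at least one deposition")
        ref = self.reference
        wn = ref.wavenumbers
        signal = n * self.amplitude * ref.absorbance
        noise = rng.normal(0.0, self.noise_sigma / np.sqrt(n), size=len(ref))
        drift = self.baseline_drift * np.sin(
            2 * np.pi * (wn - wn[0]) / (wn[-1] - wn[0]) * rng.uniform(0.5, 2.0)
            + rng.uniform(0, 2 * np.pi))
        return replace(ref, absorbance=signal + noise + drift,
                       n_depositions=n, name=f"{ref.name}+{n}dep")


NOT_REACHED = "not reached"


def median_qmf_ladder(config: DepositionSimConfig) -> list[float]:
    """Median QMF against the clean reference for n = 1..max_depositions."""
    grid = config.reference.wavenumbers
    ref = preprocess(config.reference, grid)
    medians = []
    for n in range(1, config.max_depositions + 1):
        rng = np.random.default_rng([config.seed, n])
        scores = [qmf(preprocess(config.measure(n, rng), grid), ref)
                  for _ in range(config.n_replicates)]
        medians.append(float(np.median(scores)))
    return medians


def limit_of_identification(config: DepositionSimConfig,
                            qmf_threshold: float) -> int | str:
    """Smallest deposition count whose median QMF reaches the threshold.

    Returns the sentinel ``"not reached"`` when the ladder never crosses it
    within ``config.max_depositions``.
    """
    if not 0 < qmf_threshold <= 100:
        raise DomainError("threshold must be in (0, 100]")
    for n, score in enumerate(median_qmf_ladder(config), start=1):
        if score >= qmf_threshold:
            return n
    return NOT_REACHED
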