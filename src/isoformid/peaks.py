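"""Observed MS1 feature tables.

A :class:`PeakTable` holds centroided MS1 peaks as rows; rows sharing a
``feature_id`` form one chromatographic feature's isotope cluster (the
monoisotopic peak is the lowest m/z in the cluster). Per-feature product-ion
lists for the three all-ion-fragmentation collision energies (10/25/50 eV)
ride along as semicolon-separated columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .isotopes import LABELS, IsotopePattern, IsotopePeak

COLLISION_ENERGIES = (10, 25, 50)
PRODUCT_ION_COLUMNS = tuple(f"product_ions_{ce}ev" for ce in COLLISION_ENERGIES)
REQUIRED_COLUMNS = ("feature_id", "mz", "intensity", "rt_min")


@dataclass(frozen=True)
class Feature:
    """One chromatographic feature: isotope cluster + fragments."""

    feature_id: str
    mzs: tuple[float, ...]          # ascending; [0] is monoisotopic
    intensities: tuple[float, ...]
    rt_min: float
    product_ions: dict[int, tuple[float, ...]]

    @property
    def mono_mz(self) -> float:
        return self.mzs[0]

    @property
    def mono_intensity(self) -> float:
        return self.intensities[0]

    def all_product_ions(self) -> tuple[float, ...]:
        out: list[float] = []
        for ce in COLLISION_ENERGIES:
            out.extend(self.product_ions.get(ce, ()))
        return tuple(out)

    def isotope_pattern(self) -> IsotopePattern:
        """The feature's observed envelope as a normalized pattern."""
        peaks = tuple(
            IsotopePeak(LABELS[i], mz, inten)
            for i, (mz, inten) in enumerate(zip(self.mzs, self.intensities))
            if i < len(LABELS))
        return IsotopePattern(peaks).normalized()


class PeakTable:
    """Pandas-backed table of centroided MS1 peaks."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DomainError(f"peak table missing columns: {missing}")
        frame = frame.copy()
        for col in PRODUCT_ION_COLUMNS:
            if col not in frame.columns:
                frame[col] = ""
        frame["feature_id"] = frame["feature_id"].astype(str)
        for col in ("mz", "intensity", "rt_min"):
            values = pd.to_numeric(frame[col], errors="coerce")
            bad = values.isna() & frame[col].notna()
            if bad.any():
                rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
                raise DomainError(
                    f"non-numeric {col!r} values at rows {rows}")
            frame[col] = values
        if (frame["mz"] <= 0).any():
            raise DomainError("m/z values must be positive")
        if (frame["rt_min"] < 0).any():
            raise DomainError("retention times must be non-negative")
        if (frame["intensity"] < 0).any():
            raise DomainError("intensities must be non-negative")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def features(self) -> list[Feature]:
        """Group rows into features (isotope clusters), m/z ascending."""
        out = []
        for fid, grp in self.frame.groupby("feature_id", sort=True):
            grp = grp.sort_values("mz")
            ions = {}
            first = grp.iloc[0]
            for ce, col in zip(COLLISION_ENERGIES, PRODUCT_ION_COLUMNS):
                raw = first.get(col, "")
                if isinstance(raw, str) and raw.strip():
                    ions[ce] = tuple(float(x) for x in raw.split(";") if x.strip())
            out.append(Feature(
                feature_id=str(fid),
                mzs=tuple(grp["mz"]),
                intensities=tuple(grp["intensity"]),
                rt_min=float(first["rt_min"]),
                product_ions=ions,
            ))
        return out
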