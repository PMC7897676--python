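"""Delimited-text readers/writers and run configuration.

Peak tables travel as CSV with a fixed header (feature_id, mz, intensity,
rt_min, product_ions_{10,25,50}ev with semicolon-separated values); reports
are written back as CSV. IR spectra go through :mod:`isoformid.jcampdx`.
Malformed input is reported with row numbers, never silently coerced.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .jcampdx import read_ir, write_ir  # re-exported  # noqa: F401
from .peaks import REQUIRED_COLUMNS, PeakTable


def read_peak_table(path: str | Path) -> PeakTable:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"feature_id": str},
                            keep_default_na=False,
                            float_precision="round_trip")
    except Exception as exc:
        raise DomainError(f"cannot parse {path.name}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DomainError(f"{path.name}: missing columns {missing}")
    return PeakTable(frame)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    frame = table.frame.copy()
    for col in ("mz",):
        frame[col] = frame[col].map(lambda v: f"{v:.6f}")
    frame.to_csv(path, index=False)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Validated tolerances and seeds shared by the CLI subcommands."""

    ppm_tolerance: float = 5.0
    pattern_ppm_tolerances: dict = field(default_factory=dict)
    ria_tolerance_pct: float = 20.0
    qmf_threshold: float = 80.0
    rt_guard_min: float = 0.1
    element_bounds: dict = field(default_factory=dict)
    depth: int = 3
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 0

    def __post_init__(self):
        for name in ("ppm_tolerance", "ria_tolerance_pct", "qmf_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for label, tol in self.pattern_ppm_tolerances.items():
            if tol <= 0:
                raise ConfigurationError(
                    f"pattern tolerance for {label} must be positive")

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path.name}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"{path.name}: unknown keys {unknown}")
    return RunConfig(**raw)
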