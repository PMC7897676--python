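"""Minimal JCAMP-DX reader/writer for IR spectra (XYDATA, AFFN only).

Covers the subset this package emits and consumes: single-block files with
``##XYDATA=(X++(Y..Y))`` tables in plain AFFN numbers, XFACTOR/YFACTOR
scaling, and evenly gridded abscissae. A two-column delimited dialect
(wavenumber<TAB>absorbance) is supported alongside. Compressed (SQZ/DIF/DUP)
ordinate forms are out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import DomainError
from .ir import IRSpectrum

log = logging.getLogger(__name__)


def write_jcamp(spectrum: IRSpectrum, path: str | Path,
                values_per_line: int = 6) -> None:
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    path = Path(path)
    yfactor = 1e-8  # store ordinates as scaled integers-ish AFFN reals
    lines = [
        f"##TITLE={spectrum.name or path.stem}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##RESOLUTION={spectrum.resolution}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor}",
        f"##FIRSTX={wn[0]}",
        f"##LASTX={wn[-1]}",
        f"##NPOINTS={len(wn)}",
        f"##FIRSTY={ab[0]}",
        "##XYDATA=(X++(Y..Y))",
    ]
    scaled = np.round(ab / yfactor).astype(np.int64)
    for i in range(0, len(wn), values_per_line):
        chunk = scaled[i:i + values_per_line]
        lines.append(" ".join([f"{wn[i]:.6g}"] + [str(v) for v in chunk]))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def read_jcamp(path: str | Path) -> IRSpectrum:
    path = Path(path)
    title = path.stem
    xfactor = yfactor = 1.0
    resolution = 4.0
    xs: list[float] = []
    ys: list[float] = []
    in_table = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "TITLE" and value:
                title = value
            elif key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "RESOLUTION":
                try:
                    resolution = float(value)
                except ValueError:
                    pass
            elif key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise DomainError(
                        f"{path.name}:{lineno}: unsupported XYDATA form "
                        f"{value!r}")
                in_table = True
            elif key == "END":
                in_table = False
            continue
        if not in_table:
            continue
        try:
            numbers = [float(tok) for tok in line.replace(",", " ").split()]
        except ValueError:
            raise DomainError(
                f"{path.name}:{lineno}: non-numeric XYDATA line {raw!r}")
        if len(numbers) < 2:
            raise DomainError(
                f"{path.name}:{lineno}: XYDATA line needs X plus >=1 Y")
        x0, yvals = numbers[0], numbers[1:]
        ys.extend(v * yfactor for v in yvals)
        xs.append(x0 * xfactor)
        xs.extend(np.nan for _ in yvals[1:])
    if not ys:
        raise DomainError(f"{path.name}: no XYDATA table found")
    # fill implied abscissae from consecutive anchors (even grid per segment)
    xs_arr = np.array(xs, dtype=float)
    anchors = np.flatnonzero(~np.isnan(xs_arr))
    if len(anchors) >= 2:
        step = (xs_arr[anchors[-1]] - xs_arr[anchors[0]]) / (
            anchors[-1] - anchors[0])
    else:
        step = resolution
    for i in range(len(xs_arr)):
        if np.isnan(xs_arr[i]):
            xs_arr[i] = xs_arr[i - 1] + step
    ab = np.array(ys, dtype=float)
    if len(xs_arr) >= 2 and xs_arr[0] > xs_arr[-1]:
        log.info("%s: descending wavenumbers; re-sorting ascending",
                 path.name)
        xs_arr, ab = xs_arr[::-1].copy(), ab[::-1].copy()
    order = np.argsort(xs_arr)
    return IRSpectrum(xs_arr[order], ab[order], name=title,
                      resolution=resolution)


def write_two_column(spectrum: IRSpectrum, path: str | Path,
                     delimiter: str = "\t") -> None:
    lines = [f"{x:.6g}{delimiter}{y:.10g}"
             for x, y in zip(spectrum.wavenumbers, spectrum.absorbance)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_two_column(path: str | Path) -> IRSpectrum:
    path = Path(path)
    xs, ys = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise DomainError(
                f"{path.name}:{lineno}: expected two columns, got {raw!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            raise DomainError(
                f"{path.name}:{lineno}: non-numeric value in {raw!r}")
    if not xs:
        raise DomainError(f"{path.name}: empty spectrum file")
    xs_arr, ys_arr = np.array(xs), np.array(ys)
    if xs_arr[0] > xs_arr[-1]:
        log.info("%s: descending wavenumbers; re-sorting ascending",
                 path.name)
    order = np.argsort(xs_arr)
    return IRSpectrum(xs_arr[order], ys_arr[order], name=path.stem)


def read_ir(path: str | Path) -> IRSpectrum:
    """Dispatch on extension: .jdx/.dx -> JCAMP-DX, else two-column."""
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcm", ".jcamp"):
        return read_jcamp(path)
    return read_two_column(path)


def write_ir(spectrum: IRSpectrum, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcm", ".jcamp"):
        write_jcamp(spectrum, path)
    else:
        write_two_column(spectrum, path)
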