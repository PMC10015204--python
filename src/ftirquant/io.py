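"""Reading and writing IR spectra: JCAMP-DX and two-column CSV.

JCAMP-DX support covers the subset ubiquitous in FTIR data exchange:
AFFN-encoded ``##XYDATA=(X++(Y..Y))`` tables and ``##XYPOINTS=(XY..XY)``
pair lists, with ``##XFACTOR``/``##YFACTOR`` scaling and the mode taken
from ``##YUNITS``. Compressed (SQZ/DIF/DUP) encodings are not parsed.

CSV files are two columns, ``wavenumber, intensity``, comma or tab
delimited, decimal point only, with at most one header line. The
intensity mode cannot be inferred from a bare CSV and is supplied by the
caller (default %T, the native instrument output).
"""

from __future__ import annotations

import csv as _csv
import re
from pathlib import Path

import numpy as np

from .spectra import ABSORBANCE, TRANSMITTANCE_PERCENT, Spectrum, SpectrumError

__all__ = ["read_spectrum", "read_jcamp", "read_csv", "write_jcamp", "write_csv",
           "SpectrumFormatError"]


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_spectrum(path: str | Path, format: str = "auto",
                  csv_mode: str = TRANSMITTANCE_PERCENT) -> Spectrum:
    """Read a spectrum from a JCAMP-DX or two-column CSV file.

    ``format="auto"`` dispatches on the file content: lines starting with
    ``##`` mean JCAMP-DX, anything else is tried as delimited text. For
    CSV input the intensity mode is taken from ``csv_mode``; JCAMP input
    carries its own ``##YUNITS``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        head = path.read_text(errors="replace").lstrip()
        format = "jcamp" if head.startswith("##") else "csv"
    if format == "jcamp":
        return read_jcamp(path)
    if format == "csv":
        return read_csv(path, mode=csv_mode)
    raise ValueError(f"unknown format {format!r}")


def _parse_numbers(line: str) -> list[float]:
    return [float(m) for m in _NUM.findall(line)]


def read_jcamp(path: str | Path) -> Spectrum:
    """Parse a JCAMP-DX file (AFFN XYDATA / XYPOINTS subset)."""
    path = Path(path)
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    section = None  # None | "xydata" | "xypoints"
    for lineno, raw in enumerate(path.read_text(errors="replace").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                section = "xydata"
            elif key == "XYPOINTS":
                section = "xypoints"
            elif key == "END":
                section = None
            else:
                section = None
                meta[key] = value
            continue
        if section is None:
            continue
        nums = _parse_numbers(line)
        if not nums:
            raise SpectrumFormatError(f"{path}:{lineno}: unparseable data line: {raw!r}")
        if section == "xydata":
            x0, yvals = nums[0], nums[1:]
            if not yvals:
                raise SpectrumFormatError(f"{path}:{lineno}: X value without Y values")
            # spacing from DELTAX if declared, else inferred later per line pair
            dx = _jcamp_deltax(meta)
            for i, y in enumerate(yvals):
                xs.append(x0 + i * dx)
                ys.append(y)
        else:  # xypoints
            if len(nums) % 2:
                raise SpectrumFormatError(f"{path}:{lineno}: odd number of values in XY pairs")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
    if not xs:
        raise SpectrumFormatError(f"{path}: no ##XYDATA or ##XYPOINTS block found")
    xfac = float(meta.get("XFACTOR", 1.0))
    yfac = float(meta.get("YFACTOR", 1.0))
    x = np.asarray(xs) * xfac
    y = np.asarray(ys) * yfac
    mode = _mode_from_yunits(meta.get("YUNITS", ""))
    try:
        return Spectrum(x, y, mode=mode, meta=meta)
    except SpectrumError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def _jcamp_deltax(meta: dict[str, str]) -> float:
    if "DELTAX" in meta:
        return float(meta["DELTAX"])
    try:
        first = float(meta["FIRSTX"])
        last = float(meta["LASTX"])
        npts = int(float(meta["NPOINTS"]))
        return (last - first) / (npts - 1)
    except (KeyError, ValueError, ZeroDivisionError):
        raise SpectrumFormatError(
            "XYDATA block needs ##DELTAX or ##FIRSTX/##LASTX/##NPOINTS") from None


def _mode_from_yunits(yunits: str) -> str:
    u = yunits.strip().upper()
    if "ABSORB" in u:
        return ABSORBANCE
    if "TRANSMIT" in u or u == "%T":
        return TRANSMITTANCE_PERCENT
    # default to %T, the raw instrument quantity
    return TRANSMITTANCE_PERCENT


def read_csv(path: str | Path, mode: str = TRANSMITTANCE_PERCENT) -> Spectrum:
    """Parse a two-column (wavenumber, intensity) delimited text file."""
    path = Path(path)
    text = path.read_text(errors="replace")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    xs: list[float] = []
    ys: list[float] = []
    for lineno, row in enumerate(_csv.reader(text.splitlines(), delimiter=delim), 1):
        cells = [c.strip() for c in row if c.strip()]
        if not cells:
            continue
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            if lineno == 1 and not xs:  # single optional header line
                continue
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row: {row!r}") from None
        if len(vals) != 2:
            raise SpectrumFormatError(f"{path}:{lineno}: expected 2 columns, got {len(vals)}")
        xs.append(vals[0])
        ys.append(vals[1])
    if len(xs) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    try:
        return Spectrum(np.asarray(xs), np.asarray(ys), mode=mode)
    except SpectrumError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def write_jcamp(s: Spectrum, path: str | Path, title: str = "spectrum") -> None:
    """Write a spectrum as JCAMP-DX XYPOINTS, descending grid (FTIR convention)."""
    path = Path(path)
    x = s.wavenumbers[::-1]
    y = s.intensities[::-1]
    yunits = "ABSORBANCE" if s.mode == ABSORBANCE else "TRANSMITTANCE"
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        f"##YUNITS={yunits}",
        f"##FIRSTX={x[0]:.8g}",
        f"##LASTX={x[-1]:.8g}",
        f"##NPOINTS={x.size}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{xi:.8g}, {yi:.10g}" for xi, yi in zip(x, y)]
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def write_csv(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as ascending two-column CSV with a header line."""
    path = Path(path)
    rows = ["wavenumber_cm-1,intensity"]
    rows += [f"{xi:.8g},{yi:.10g}" for xi, yi in zip(s.wavenumbers, s.intensities)]
    path.write_text("\n".join(rows) + "\n")
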