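"""Spectrum container and preprocessing for transmission mid-IR data.

A :class:`Spectrum` holds a sampled IR trace on a strictly monotonic
wavenumber grid, either in percent transmittance or in absorbance units.
Preprocessing covers the steps that precede band-area quantification:
conversion %T -> A, replicate averaging, resampling onto a common grid,
and baseline correction (rubberband or linear-endpoints).

Wavenumbers are canonicalized to ascending order internally; FTIR
convention (descending 4000 -> 400 cm^-1) is restored only when writing
JCAMP-DX files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spectrum",
    "TRANSMITTANCE_PERCENT",
    "ABSORBANCE",
    "to_absorbance",
    "average_spectra",
    "resample",
    "baseline_correct",
    "rubberband_baseline",
]

logger = logging.getLogger(__name__)

TRANSMITTANCE_PERCENT = "transmittance_percent"
ABSORBANCE = "absorbance"

#: %T values below this floor are clipped before taking log10 (A <= 6).
TRANSMITTANCE_CLIP_FLOOR = 1e-4


class SpectrumError(ValueError):
    """Raised for invalid spectral data or incompatible operations."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled IR spectrum on a strictly monotonic wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Grid in cm^-1, strictly monotonic in either direction on input;
        stored ascending.
    intensities
        Same length as ``wavenumbers``; %T or absorbance depending on
        ``mode``.
    mode
        ``"transmittance_percent"`` or ``"absorbance"``.
    meta
        Free-form string metadata (sample id, number of scans, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    mode: str = ABSORBANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or y.ndim != 1 or wn.size != y.size:
            raise SpectrumError("wavenumbers and intensities must be 1-D and equal length")
        if wn.size < 2:
            raise SpectrumError("a spectrum needs at least two points")
        d = np.diff(wn)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            wn, y = wn[::-1], y[::-1]
        else:
            raise SpectrumError("wavenumber grid must be strictly monotonic")
        if self.mode not in (TRANSMITTANCE_PERCENT, ABSORBANCE):
            raise SpectrumError(f"unknown mode {self.mode!r}")
        if self.mode == ABSORBANCE and not np.all(np.isfinite(y)):
            raise SpectrumError("absorbance intensities must be finite")
        wn.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def range(self) -> tuple[float, float]:
        """(min, max) wavenumber in cm^-1."""
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def with_intensities(self, y: np.ndarray, mode: str | None = None,
                         **meta_updates: str) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(y, dtype=float),
                        mode=mode or self.mode, meta={**self.meta, **meta_updates})


def to_absorbance(s: Spectrum) -> Spectrum:
    """Convert a %-transmittance spectrum to absorbance, A = 2 - log10(%T).

    Idempotent: an absorbance spectrum is returned as a copy. %T values
    below ``TRANSMITTANCE_CLIP_FLOOR`` are clipped (and logged) before the
    logarithm; negative %T is a data error.
    """
    if s.mode == ABSORBANCE:
        return replace(s)
    t = s.intensities
    if np.any(t < 0):
        raise SpectrumError("negative %T values cannot be converted to absorbance")
    n_clip = int(np.count_nonzero(t < TRANSMITTANCE_CLIP_FLOOR))
    if n_clip:
        logger.warning("clipped %d %%T values below %g before log10", n_clip,
                       TRANSMITTANCE_CLIP_FLOOR)
        if n_clip == t.size:
            warnings.warn("entire spectrum at or below the %T clip floor", stacklevel=2)
    a = 2.0 - np.log10(np.clip(t, TRANSMITTANCE_CLIP_FLOOR, None))
    return s.with_intensities(a, mode=ABSORBANCE)


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (must lie inside its range).

    Exact where grid points coincide with original samples; extrapolation is
    refused.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.range
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise SpectrumError(
            f"resample grid [{grid.min():g}, {grid.max():g}] outside spectrum "
            f"range [{lo:g}, {hi:g}] (extrapolation not supported)")
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, y, mode=s.mode, meta=dict(s.meta))


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra.

    All spectra must share a mode. Unequal grids are resampled onto the
    first spectrum's grid restricted to the range common to all inputs.
    The result's metadata records ``n_averaged``.
    """
    if not spectra:
        raise SpectrumError("average_spectra requires at least one spectrum")
    mode = spectra[0].mode
    if any(s.mode != mode for s in spectra):
        raise SpectrumError("cannot average spectra with mixed intensity modes")
    lo = max(s.range[0] for s in spectra)
    hi = min(s.range[1] for s in spectra)
    if lo >= hi:
        raise SpectrumError("spectra have no overlapping wavenumber range")
    ref = spectra[0].wavenumbers
    grid = ref[(ref >= lo) & (ref <= hi)]
    if grid.size < 2:
        raise SpectrumError("overlapping range covers fewer than two grid points")
    stack = np.vstack([resample(s, grid).intensities for s in spectra])
    out = Spectrum(grid, stack.mean(axis=0), mode=mode, meta=dict(spectra[0].meta))
    out.meta["n_averaged"] = str(len(spectra))
    return out


def rubberband_baseline(s: Spectrum) -> np.ndarray:
    """Lower convex hull of the absorbance trace, evaluated on its grid.

    The hull is computed by a monotone-chain scan over (wavenumber,
    absorbance) points and linearly interpolated between hull vertices;
    it touches the signal at every vertex, so the corrected spectrum is
    zero there and >= 0 in between for convex-deficient regions.
    """
    x, y = s.wavenumbers, s.intensities
    if x.size < 3:
        raise SpectrumError("rubberband baseline needs at least three points")
    # monotone chain, lower hull: pop while the turn is clockwise or straight
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    idx = np.asarray(hull)
    return np.interp(x, x[idx], y[idx])


def baseline_correct(s: Spectrum, method: str = "rubberband") -> Spectrum:
    """Subtract an estimated baseline from an absorbance spectrum.

    Methods
    -------
    ``rubberband``
        Lower convex hull of the trace (parameter-free, instrument-style
        automatic correction). Default.
    ``linear_endpoints``
        Straight line through the first and last sample.
    ``none``
        Identity.
    """
    if s.mode != ABSORBANCE:
        raise SpectrumError("baseline correction operates on absorbance spectra")
    if method == "none":
        return replace(s)
    if method == "rubberband":
        base = rubberband_baseline(s)
    elif method == "linear_endpoints":
        x, y = s.wavenumbers, s.intensities
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    else:
        raise SpectrumError(f"unknown baseline method {method!r}")
    return s.with_intensities(s.intensities - base, baseline=method)
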