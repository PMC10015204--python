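"""Seeded synthetic mixture IR spectra with Beer-Lambert structure.

The generator emulates transmission FTIR spectra of two-component
pharmaceutical mixtures in a halide pellet: each component contributes a
set of vibrational bands (Gaussian or Lorentzian line shapes) whose
amplitudes scale linearly with concentration, on top of an affine
baseline drift and additive i.i.d. Gaussian noise in absorbance. A fixed
seed makes every spectrum bit-reproducible.

The default component libraries place the amlodipine besylate and
atorvastatin calcium bands at their observed mid-IR positions (carbonyl
stretches at 1697.98 and 1651.61 cm^-1 driving the quantification
windows, plus O-H/N-H, aromatic C-H, C=C and C-O bands elsewhere), with
amplitudes scaled so a 0.5% w/w standard yields in-window band areas of
about 5.5 (AML) and 7.9 (ATV) — the magnitudes a real calibration at
those levels produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .spectra import ABSORBANCE, Spectrum

__all__ = [
    "BandSpec",
    "MixtureDesign",
    "AML_BANDS",
    "ATV_BANDS",
    "EXCIPIENT_BANDS",
    "default_design",
    "synth_spectrum",
    "make_calibration_set",
]


@dataclass(frozen=True)
class BandSpec:
    """One synthetic absorption band.

    ``unit_amplitude`` is the peak absorbance contributed at 1% w/w;
    ``width`` is the Gaussian sigma or Lorentzian half-width gamma in
    cm^-1.
    """

    center: float
    width: float
    unit_amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.unit_amplitude < 0:
            raise ValueError("unit amplitude must be nonnegative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-concentration absorbance profile on the given grid."""
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            return self.unit_amplitude * np.exp(-0.5 * (d / self.width) ** 2)
        return self.unit_amplitude * self.width ** 2 / (d ** 2 + self.width ** 2)

    @property
    def area(self) -> float:
        """Analytic unit-concentration integral over the whole axis."""
        if self.shape == "gaussian":
            return self.unit_amplitude * self.width * math.sqrt(2.0 * math.pi)
        return self.unit_amplitude * self.width * math.pi


# Carbonyl amplitudes chosen so a 0.5% w/w standard gives in-window AUC
# near 5.5 (AML, 1688-1708) and 7.9 (ATV, 1632-1660); the remaining bands
# use smaller amplitudes typical of the relative intensities seen in the
# pure-component spectra. All widths sigma = 6 cm^-1.
AML_BANDS: tuple[BandSpec, ...] = (
    BandSpec(3364.70, 6.0, 0.20),   # O-H
    BandSpec(3299.13, 6.0, 0.25),   # N-H
    BandSpec(3068.28, 6.0, 0.12),   # aromatic C-H
    BandSpec(3056.09, 6.0, 0.12),
    BandSpec(1697.98, 6.0, 0.806),  # ester C=O — quantification band
    BandSpec(1674.92, 6.0, 0.30),   # second carbonyl
    BandSpec(1615.72, 6.0, 0.25),   # aromatic C=C
    BandSpec(1595.18, 6.0, 0.22),
    BandSpec(1017.62, 6.0, 0.30),   # C-O
)

ATV_BANDS: tuple[BandSpec, ...] = (
    BandSpec(3365.01, 6.0, 0.22),   # O-H
    BandSpec(3228.00, 6.0, 0.20),   # N-H
    BandSpec(3088.73, 6.0, 0.10),   # aromatic C-H
    BandSpec(3064.39, 6.0, 0.10),
    BandSpec(1651.61, 6.0, 1.145),  # amide C=O — quantification band
    BandSpec(1615.27, 6.0, 0.20),   # aromatic C=C
    BandSpec(1595.50, 6.0, 0.18),
    BandSpec(1017.52, 6.0, 0.28),   # C-O
)

#: Interference bands mimicking common tablet excipients (carbonate,
#: cellulose/starch O-H and C-O, aliphatic C-H) — all outside both
#: quantification windows.
EXCIPIENT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(3350.0, 40.0, 0.15),   # broad polysaccharide O-H
    BandSpec(2900.0, 15.0, 0.10),   # aliphatic C-H
    BandSpec(1430.0, 20.0, 0.25),   # carbonate
    BandSpec(1050.0, 25.0, 0.30),   # C-O skeletal
    BandSpec(875.0, 8.0, 0.10),     # carbonate out-of-plane
)


@dataclass(frozen=True)
class MixtureDesign:
    """Full specification of one synthetic mixture spectrum.

    ``components`` maps an analyte label to its band library and its
    concentration in % w/w. ``baseline`` is (offset, slope per cm^-1)
    absorbance drift; ``grid`` is (start, stop, step) in cm^-1 and may
    run in either direction; ``noise_sd`` is the additive absorbance
    noise. The same seed always reproduces the same spectrum.
    """

    components: dict[str, tuple[tuple[BandSpec, ...], float]]
    noise_sd: float = 0.0
    baseline: tuple[float, float] = (0.0, 0.0)
    grid: tuple[float, float, float] = (400.0, 4000.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (bands, conc) in self.components.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name}")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.grid
        lo, hi = min(start, stop), max(start, stop)
        return np.arange(lo, hi + step / 2, step)


#: Default simulated noise level, absorbance units. At the default grid
#: this propagates to replicate band-area RSDs near 1% for a 0.5% w/w
#: standard, matching the repeatability a well-behaved pellet series shows.
DEFAULT_NOISE_SD = 0.008

#: Default baseline drift: small offset plus a gentle slope across the range.
DEFAULT_BASELINE = (0.01, 2e-6)


def default_design(aml_pct: float = 0.5, atv_pct: float = 0.5,
                   excipient_pct: float = 0.0,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   baseline: tuple[float, float] = DEFAULT_BASELINE,
                   grid: tuple[float, float, float] = (400.0, 4000.0, 2.0),
                   seed: int = 0) -> MixtureDesign:
    """Convenience two-analyte design with the default band libraries."""
    components = {
        "AML": (AML_BANDS, aml_pct),
        "ATV": (ATV_BANDS, atv_pct),
    }
    if excipient_pct > 0:
        components["excipients"] = (EXCIPIENT_BANDS, excipient_pct)
    return MixtureDesign(components=components, noise_sd=noise_sd,
                         baseline=baseline, grid=grid, seed=seed)


def synth_spectrum(d: MixtureDesign) -> Spectrum:
    """Render one absorbance spectrum from a mixture design.

    A(nu) = offset + slope*nu
            + sum over components of conc * sum of band profiles
            + N(0, noise_sd),
    evaluated on the design grid with the design seed.
    """
    wn = d.wavenumbers()
    a = d.baseline[0] + d.baseline[1] * wn
    for bands, conc in d.components.values():
        if conc == 0:
            continue
        for band in bands:
            a = a + conc * band.profile(wn)
    if d.noise_sd > 0:
        rng = np.random.default_rng(d.seed)
        a = a + rng.normal(0.0, d.noise_sd, size=wn.size)
    meta = {"synthetic": "true", "seed": str(d.seed),
            **{f"conc_{k}": repr(v[1]) for k, v in d.components.items()}}
    return Spectrum(wn, a, mode=ABSORBANCE, meta=meta)


def make_calibration_set(levels: list[float], replicates: int,
                         template: MixtureDesign,
                         ) -> list[tuple[float, list[Spectrum]]]:
    """Generate a replicate calibration series from a design template.

    Every analyte in the template is set to each level in turn (the
    standards are equal-concentration mixtures); each replicate gets an
    independent noise realization via a seed derived from the template
    seed, so the whole set is reproducible.
    """
    if len(set(levels)) != len(levels) or any(l <= 0 for l in levels):
        raise ValueError("levels must be distinct and positive")
    if replicates < 1:
        raise ValueError("at least one replicate per level")
    ss = np.random.SeedSequence(template.seed)
    child_seeds = iter(s.generate_state(1)[0] % (2 ** 31) for s in
                      ss.spawn(len(levels) * replicates))
    out = []
    for level in levels:
        comps = {name: (bands, level) for name, (bands, _) in template.components.items()}
        reps = []
        for _ in range(replicates):
            d = replace(template, components=comps, seed=int(next(child_seeds)))
            reps.append(synth_spectrum(d))
        out.append((level, reps))
    return out
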