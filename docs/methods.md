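# Methods

## Model

The package quantifies two analytes from one transmission mid-IR
spectrum under the Beer–Lambert assumption: at fixed path length (a
pressed halide pellet of fixed mass), the absorbance contributed by an
analyte at every wavenumber is proportional to its concentration, so the
integrated absorbance over a band window is linear in concentration,

    AUC_w(c) = a·c + b,

with the intercept absorbing residual baseline and matrix contributions.
Each analyte gets its own window chosen where the other analyte and the
excipients are transparent — the carbonyl stretches at 1688–1708 cm⁻¹
(amlodipine besylate, band maximum ≈ 1697 cm⁻¹) and 1632–1660 cm⁻¹
(atorvastatin calcium, ≈ 1650 cm⁻¹). Under window-disjointness the two
univariate calibrations are independent and no multivariate model is
needed; overlapping bands are explicitly out of scope (no deconvolution,
no PLS/PCR).

## Preprocessing pipeline

1. **%T → A**: A = 2 − log₁₀(%T). %T is clipped below at 1e-4 before the
   logarithm (capping A at 6) and clipping is logged; negative %T is a
   data error. Grids are canonicalized ascending internally; JCAMP-DX
   output is written descending per FTIR convention.
2. **Replicate averaging**: pointwise mean. Unequal grids are resampled
   (linear interpolation, no extrapolation) onto the first spectrum's
   grid restricted to the common range — deterministic and
   order-documented.
3. **Baseline**: the instrument-style automatic correction is modelled as
   a rubberband — the lower convex hull of the absorbance trace
   (monotone-chain scan), linearly interpolated between hull vertices and
   subtracted. It is parameter-free, exact on flat or affine signals, and
   invariant (to 1e-9) to adding any affine function of wavenumber when
   the bands are interior to the range. A linear-endpoints baseline and
   `none` are offered for per-window use. Which algorithm the original
   instrument software applies is not documented; rubberband is this
   package's choice and is flagged as such.
4. **Integration**: trapezoid on the native grid with exact linear
   interpolation at the window limits. The default "abscissa" mode
   integrates against the zero line (the band-area rule of the
   instrument software); "endpoints" mode subtracts the chord through
   the window edges first, for use when no global baseline was removed.
   Integration is additive over window partitions (1e-9), linear in the
   signal, and converges at second order in the grid spacing.

## Calibration and prediction

Unweighted ordinary least squares of AUC against concentration
(scipy.stats.linregress), responses being the per-level replicate means
by default — the convention the reference tables use and the one that
reproduces their printed coefficients; fitting all replicates is
available and yields slightly different correlation statistics. A model
requires ≥ 3 distinct levels. Inverse prediction is x = (y − b)/a;
negative or below-LOQ predictions are returned as-is and flagged by the
caller, never suppressed. Reported coefficients are rounded half-up at
printed precision; full precision is kept internally.

## Validation statistics

- **Replicate stats**: mean, SD, RSD = 100·SD/mean. The SD divisor is an
  explicit parameter everywhere: *population* (n) reproduces the
  reference triplicate AUC tables; *sample* (n−1) is the default for
  inferential use. It is never chosen silently.
- **Accuracy**: standard-addition recoveries per level, mean ± SD, gate
  98–102%.
- **Precision**: per-group mean/SD/RSD with a 2% RSD gate; the same
  builder serves the ten-replicate repeatability layout and the
  per-day/per-level intermediate-precision layout.
- **LOD/LOQ**: 3·SD·C/M and 10·SD·C/M from replicate band areas of the
  lowest distinguishable standard; the 10/3 ratio is exact by
  construction.
- **Specificity**: for equal-concentration pure references, the fraction
  of the *other* component's AUC inside each assigned window; both
  fractions ≤ 0.05 (configurable) flags the method specific. The
  threshold is this package's quantitative reading of a qualitative
  "no interfering band" criterion.
- **Tablet assay**: mg/tablet = (predicted %·pellet mass − spiked
  amount)·(tablet mass / sampled mass); spiked samples must state the
  spike explicitly. Compliance bands are per-analyte configuration with
  defaults 90–110% (AML) and 94.5–105% (ATV) of label claim.
- **Method comparison**: F = (larger SD/smaller SD)², compared against
  the upper 1−α/2 quantile of F(n_hi−1, n_lo−1) or an explicit tabulated
  value. The t test offers the pooled form (df = n_a+n_b−2) and Welch's
  form; critical values come from scipy's t distribution, with an
  override for report-tabulated figures. Pooled-t results on the bundled
  comparison summaries do not match that report's printed t values —
  those are not reproducible from the printed means/SDs/n under either
  form (the pooled formula gives 2.877 where 0.114 is printed) — so the
  t operation is validated against brute-force recomputation from raw
  samples instead. One printed F value (1.784) differs from its own
  SDs by one unit in the last digit; tests allow that 0.002.

## Synthetic spectra

`simulate` renders A(ν) = baseline(ν) + Σ_k c_k Σ_j amp_kj·g(ν; center_kj,
width_kj) + ε, ε ~ N(0, σ²) i.i.d., with Gaussian or Lorentzian line
shapes. Defaults:

- **Band centers**: the observed AML/ATV mid-IR band positions (carbonyl,
  O–H/N–H, aromatic C–H, C=C, C–O). Widths are not tabulated anywhere, so
  all bands use σ = 6 cm⁻¹, a typical solid-state carbonyl width at 4 cm⁻¹
  instrument resolution.
- **Amplitudes**: carbonyl amplitudes scaled so a 0.5 % w/w standard gives
  in-window AUC ≈ 5.5 (AML) and ≈ 7.9 (ATV), matching the magnitudes of
  the reference calibration tables; other bands are proportionally
  weaker.
- **Noise**: σ = 0.008 absorbance, set once so triplicate band-area RSDs
  land near 1%, the repeatability a well-behaved pellet series shows.
- **Baseline drift**: offset 0.01 + 2·10⁻⁶·ν, a gentle affine tilt the
  rubberband removes exactly.
- **Grid**: 4000–400 cm⁻¹ at 2 cm⁻¹ — finer than the 4 cm⁻¹ instrument
  resolution so resampling paths are exercised.
- **Seeding**: one integer seed per design; calibration sets derive
  per-replicate child seeds via `numpy.random.SeedSequence.spawn`, so a
  set is reproducible file-for-file.
- An excipient band library (carbonate, polysaccharide O–H/C–O, aliphatic
  C–H) sits entirely outside both windows; at 1 % w/w it moves either
  analyte's AUC by < 1%, emulating the specificity finding.

What the generator does **not** model: scattering and pellet
inhomogeneity, ATR/Mie artifacts, instrument line-shape convolution,
atmospheric CO₂/H₂O bands, wavenumber miscalibration, and band-shape
changes with concentration (hydrogen bonding). Passing synthetic tests
therefore demonstrates the correctness of the numerics and the
statistical pipeline, not robustness to those physical effects.

## Numerical choices and problem sizes

- Peak search returns the grid point of maximal in-window absorbance,
  ties broken toward higher wavenumber; window edges participate via
  interpolated values.
- Report rounding is decimal half-up (2 dp for percentages, 3 dp for
  concentrations and t/F), matching how printed tables round.
- The end-to-end slope-recovery experiment runs 500 seeded synthetic
  calibrations (7 levels × 3 replicates) on a 1500–1800 cm⁻¹ grid — the
  carbonyl region, which contains everything the band areas see — and
  checks the fitted slope against the noiseless-truth slope within 3
  standard errors, the SE taken from a 500-replicate Monte Carlo estimate
  of the band-area noise so the 3-SE band keeps its nominal ~99.7%
  coverage. Observed pass rates are 0.992–1.0 across seeds against the
  ≥ 0.99 gate.

## Known limitations

- JCAMP-DX support covers AFFN `(X++(Y..Y))` and `(XY..XY)` tables only;
  SQZ/DIF/DUP compression and multi-block files are not parsed.
- The calibration is strictly univariate; any real band overlap between
  analytes or with excipients biases both models and is only *detected*
  (specificity check), not corrected.
- LOD/LOQ are as good as the low-standard replicate SD supplied; the
  package does not model the detection decision itself.
- Intermediate precision is summarized per day/level; no variance-
  component (ANOVA) decomposition is performed.
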