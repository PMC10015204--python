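"""ICH Q2-style validation statistics for a two-analyte FTIR assay.

Covers the validation characteristics a quality-control method report
needs: replicate descriptive statistics (mean / SD / RSD), percent
recovery with acceptance bands, accuracy tables from standard-addition
designs, repeatability and intermediate-precision summaries, detection
and quantification limits (LOD = 3*SD*C/M, LOQ = 10*SD*C/M), tablet
assay arithmetic with pharmacopeial compliance ranges, and two-sample
t / F comparison against a reference method.

SD convention matters and is never chosen silently: the triplicate AUC
tables of the underlying study use the population SD (divisor n); sample
SD (divisor n-1) is the default for inferential statistics. Every
function takes the convention explicitly where it applies.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ReplicateSet",
    "MethodSummary",
    "AssayResult",
    "replicate_stats",
    "recovery",
    "lod_loq",
    "compare_methods_f",
    "compare_methods_t",
    "accuracy_report",
    "precision_report",
    "assay_report",
    "mg_per_tablet",
    "round_half_up",
    "DEFAULT_RECOVERY_BAND",
    "COMPLIANCE_BANDS",
]

#: Standard-addition accuracy acceptance band, % recovery.
DEFAULT_RECOVERY_BAND = (98.0, 102.0)

#: Pharmacopeial assay compliance ranges, % of label claim, per analyte.
COMPLIANCE_BANDS = {"AML": (90.0, 110.0), "ATV": (94.5, 105.0)}

#: Repeatability / intermediate precision acceptance gate, RSD %.
RSD_GATE = 2.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero), as printed reports use."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ReplicateSet:
    """A labeled group of repeated measurements (AUCs or found concentrations)."""

    values: tuple[float, ...]
    label: str = ""
    sd_convention: str = "sample"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) < 2:
            raise ValueError("a replicate set needs n >= 2 for any SD")
        if self.sd_convention not in ("population", "sample"):
            raise ValueError(f"unknown sd_convention {self.sd_convention!r}")

    @property
    def n(self) -> int:
        return len(self.values)


def replicate_stats(r: ReplicateSet) -> tuple[float, float, float]:
    """(mean, SD, RSD %) under the set's SD convention.

    RSD = 100 * SD / mean; undefined (raises) for zero mean.
    """
    v = np.asarray(r.values)
    mean = float(v.mean())
    sd = float(v.std(ddof=0 if r.sd_convention == "population" else 1))
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return mean, sd, 100.0 * sd / mean


def recovery(found: float, reference: float,
             band: tuple[float, float] = DEFAULT_RECOVERY_BAND) -> tuple[float, bool]:
    """Percent recovery 100*found/reference and its acceptance flag."""
    if reference <= 0:
        raise ValueError("reference amount must be positive")
    pct = 100.0 * found / reference
    return pct, band[0] <= pct <= band[1]


def lod_loq(sd: float, concentration: float, mean_area: float) -> tuple[float, float]:
    """Detection and quantification limits from a low standard's band areas.

    LOD = 3*SD*C/M and LOQ = 10*SD*C/M, where SD is the band-area standard
    deviation, C the standard's concentration (% w/w) and M its mean band
    area. LOQ/LOD is 10/3 by construction.
    """
    if mean_area == 0:
        raise ZeroDivisionError("mean band area must be nonzero")
    if sd < 0 or concentration <= 0 or mean_area < 0:
        raise ValueError("SD >= 0, C > 0 and M >= 0 required")
    lod = 3.0 * sd * concentration / mean_area
    loq = 10.0 * sd * concentration / mean_area
    return lod, loq


@dataclass(frozen=True)
class MethodSummary:
    """Summary statistics of one method's recoveries: mean, SD, n."""

    mean: float
    sd: float
    n: int
    method_name: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("method summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")


def compare_methods_f(a: MethodSummary, b: MethodSummary,
                      alpha: float = 0.05,
                      critical_value: float | None = None) -> tuple[float, bool]:
    """Variance-ratio F test between two methods.

    F = (larger SD / smaller SD)^2, so F >= 1 and the statistic is
    symmetric in its arguments. Significance is judged against the
    upper-tail critical value of F(n_hi-1, n_lo-1) at the two-sided
    ``alpha`` (i.e. quantile 1 - alpha/2), or against an explicit
    ``critical_value`` such as a report's tabulated figure.
    """
    hi, lo = (a, b) if a.sd >= b.sd else (b, a)
    if lo.sd == 0:
        import warnings
        warnings.warn("zero SD in denominator: F is infinite, flagged significant",
                      stacklevel=2)
        return float("inf"), True
    f = (hi.sd / lo.sd) ** 2
    if critical_value is None:
        critical_value = float(_st.f.ppf(1 - alpha / 2, hi.n - 1, lo.n - 1))
    return f, f > critical_value


def compare_methods_t(a: MethodSummary, b: MethodSummary,
                      variant: str = "pooled",
                      alpha: float = 0.05,
                      critical_value: float | None = None) -> tuple[float, float, bool]:
    """Two-sample t test on summary statistics: (t, df, significant).

    ``pooled``: t = |mean_a - mean_b| / (s_p * sqrt(1/n_a + 1/n_b)) with
    s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2) and
    df = n_a + n_b - 2. ``welch``: unequal-variance form with
    Welch-Satterthwaite df. Critical value from the t distribution at
    two-sided ``alpha`` unless overridden.
    """
    diff = abs(a.mean - b.mean)
    if a.sd == 0 and b.sd == 0:
        t = 0.0 if diff == 0 else float("inf")
        df = float(a.n + b.n - 2)
        return t, df, t > 0
    va, vb = a.sd ** 2, b.sd ** 2
    if variant == "pooled":
        df = float(a.n + b.n - 2)
        sp = np.sqrt(((a.n - 1) * va + (b.n - 1) * vb) / df)
        t = diff / (sp * np.sqrt(1.0 / a.n + 1.0 / b.n))
    elif variant == "welch":
        se2 = va / a.n + vb / b.n
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1))
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if critical_value is None:
        critical_value = float(_st.t.ppf(1 - alpha / 2, df))
    return float(t), float(df), bool(t > critical_value)


def accuracy_report(levels: list[tuple[float, ReplicateSet]],
                    band: tuple[float, float] = DEFAULT_RECOVERY_BAND) -> pd.DataFrame:
    """Standard-addition accuracy table: per-level recovery plus overall stats.

    ``levels`` pairs the added amount with the replicate set of found
    amounts. The report carries per-level mean found, recovery %, a
    pass flag against ``band``, and a summary row with mean recovery,
    SD (same convention as the replicate sets) and RSD.
    """
    if not levels:
        raise ValueError("accuracy report needs at least one level")
    rows = []
    recoveries = []
    for added, found_set in levels:
        mean_found = float(np.mean(found_set.values))
        rec, ok = recovery(mean_found, added, band)
        recoveries.append(rec)
        rows.append({"added": added, "found_mean": mean_found, "n": found_set.n,
                     "recovery_pct": rec, "pass": ok})
    df = pd.DataFrame(rows)
    conv = levels[0][1].sd_convention
    rec_arr = np.asarray(recoveries)
    sd = float(rec_arr.std(ddof=0 if conv == "population" else 1)) if len(recoveries) > 1 else 0.0
    df.attrs["mean_recovery"] = float(rec_arr.mean())
    df.attrs["recovery_sd"] = sd
    df.attrs["recovery_rsd"] = 100.0 * sd / float(rec_arr.mean())
    df.attrs["accepted"] = bool(df["pass"].all())
    return df


def precision_report(groups: dict[str, ReplicateSet],
                     rsd_gate: float = RSD_GATE) -> pd.DataFrame:
    """Repeatability / intermediate-precision table, one row per group.

    ``groups`` maps a label (a concentration level, or a day/level pair for
    intermediate precision) to its replicate set. Each row reports mean,
    SD, RSD %, and a pass flag against the RSD gate (default 2%); the
    frame's ``attrs["accepted"]`` is the conjunction.
    """
    if not groups:
        raise ValueError("precision report needs at least one replicate group")
    rows = []
    for label, rset in groups.items():
        mean, sd, rsd = replicate_stats(rset)
        rows.append({"group": label, "n": rset.n, "mean": mean, "sd": sd,
                     "rsd_pct": rsd, "pass": rsd <= rsd_gate})
    df = pd.DataFrame(rows)
    df.attrs["accepted"] = bool(df["pass"].all())
    return df


def mg_per_tablet(predicted_pct: float, pellet_mass_mg: float,
                  sample_mass_mg: float, tablet_mass_mg: float,
                  spiked_mg: float = 0.0) -> float:
    """Convert a predicted pellet concentration to mg of analyte per tablet.

    Analyte in the pellet is ``predicted_pct/100 * pellet_mass_mg``; any
    amount spiked into the pellet during preparation (e.g. standard added
    to equalize the two analytes) is subtracted before scaling from the
    sampled powder mass to a whole tablet.
    """
    if pellet_mass_mg <= 0 or sample_mass_mg <= 0 or tablet_mass_mg <= 0:
        raise ValueError("masses must be positive")
    in_pellet = predicted_pct / 100.0 * pellet_mass_mg
    from_sample = in_pellet - spiked_mg
    return from_sample * tablet_mass_mg / sample_mass_mg


@dataclass(frozen=True)
class AssayResult:
    """Per-sample tablet assay outcome vs the label claim."""

    analyte: str
    labeled_mg: float
    found_mg: float
    found_sd: float
    recovery_pct: float
    compliant: bool


def assay_report(samples: list[dict],
                 compliance_bands: dict[str, tuple[float, float]] | None = None,
                 ) -> list[AssayResult]:
    """Tablet assay table: found vs labeled content with compliance flags.

    Each sample dict carries ``analyte``, ``labeled_mg`` and either
    ``found_mg`` (+ optional ``found_sd``) directly, or the sample-prep
    arithmetic inputs ``predicted_pct, pellet_mass_mg, sample_mass_mg,
    tablet_mass_mg`` (+ optional ``spiked_mg``) from which found_mg is
    computed via :func:`mg_per_tablet`. A sample prepared with a spike
    must state ``spiked_mg`` explicitly.
    """
    bands = compliance_bands or COMPLIANCE_BANDS
    results = []
    for smp in samples:
        analyte = smp["analyte"]
        labeled = float(smp["labeled_mg"])
        if labeled <= 0:
            raise ValueError("labeled content must be positive")
        if "found_mg" in smp:
            found = float(smp["found_mg"])
        else:
            if smp.get("spiked") and "spiked_mg" not in smp:
                raise ValueError(f"sample {smp} was spiked but spiked_mg is missing")
            found = mg_per_tablet(
                smp["predicted_pct"], smp["pellet_mass_mg"],
                smp["sample_mass_mg"], smp["tablet_mass_mg"],
                spiked_mg=smp.get("spiked_mg", 0.0))
        band = bands.get(analyte, (90.0, 110.0))
        rec, _ = recovery(found, labeled, band)
        results.append(AssayResult(
            analyte=analyte, labeled_mg=labeled, found_mg=found,
            found_sd=float(smp.get("found_sd", 0.0)),
            recovery_pct=rec, compliant=band[0] <= rec <= band[1]))
    return results
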