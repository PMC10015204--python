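"""Beer-Lambert univariate calibration: OLS fit, diagnostics, inverse prediction.

The calibration line relates the band AUC (response y) to analyte
concentration (x, % w/w in the pellet): y = a*x + b, fit by unweighted
ordinary least squares. Concentration of an unknown is recovered by
inverse prediction x = (y - b) / a.

By convention the fit uses the replicate-mean AUC at each level
(``response="replicate_means"``); fitting every replicate individually is
available and gives slightly different correlation statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BandWindow

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "fit_calibration",
    "regression_stats",
    "predict_concentration",
    "read_calibration_csv",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: concentration (% w/w) and replicate AUCs."""

    concentration: float
    auc_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("calibration concentration must be positive")
        if len(self.auc_replicates) < 1:
            raise ValueError("at least one AUC replicate is required")
        object.__setattr__(self, "auc_replicates", tuple(float(v) for v in self.auc_replicates))

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_replicates))

    def auc_sd(self, sd_convention: str = "population") -> float:
        """Replicate SD; ``population`` (n) or ``sample`` (n-1) divisor."""
        ddof = 0 if sd_convention == "population" else 1
        return float(np.std(self.auc_replicates, ddof=ddof))


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted Beer-Lambert line for one analyte/window."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    n_points: int
    residuals: tuple[float, ...]
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    analyte: str = ""
    window: BandWindow | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "analyte": self.analyte,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "concentrations": list(self.concentrations),
            "responses": list(self.responses),
        }
        if self.window is not None:
            d["window"] = {"lo": self.window.lo, "hi": self.window.hi,
                           "label": self.window.label}
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        win = d.get("window")
        conc = tuple(d["concentrations"])
        resp = tuple(d["responses"])
        resid = tuple(y - (d["slope"] * x + d["intercept"]) for x, y in zip(conc, resp))
        return cls(slope=d["slope"], intercept=d["intercept"], r=d["r"],
                   r_squared=d["r_squared"], n_points=d["n_points"],
                   residuals=resid, concentrations=conc, responses=resp,
                   analyte=d.get("analyte", ""),
                   window=BandWindow(**win) if win else None)


def fit_calibration(points: list[CalibrationPoint],
                    response: str = "replicate_means",
                    analyte: str = "",
                    window: BandWindow | None = None) -> CalibrationModel:
    """Ordinary least squares of AUC response against concentration.

    ``response="replicate_means"`` fits the per-level mean AUCs (one point
    per level); ``"all_replicates"`` fits every replicate individually.
    At least three distinct concentrations are required.
    """
    if len({p.concentration for p in points}) < 3:
        raise ValueError("calibration needs at least three distinct concentrations")
    if response == "replicate_means":
        x = np.array([p.concentration for p in points])
        y = np.array([p.auc_mean for p in points])
    elif response == "all_replicates":
        x = np.array([p.concentration for p in points for _ in p.auc_replicates])
        y = np.array([v for p in points for v in p.auc_replicates])
    else:
        raise ValueError(f"unknown response mode {response!r}")
    if np.ptp(x) == 0:
        raise ValueError("all concentrations equal: singular design")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue ** 2),
        n_points=int(x.size),
        residuals=tuple((y - fitted).tolist()),
        concentrations=tuple(x.tolist()),
        responses=tuple(y.tolist()),
        analyte=analyte,
        window=window,
    )


def regression_stats(m: CalibrationModel) -> dict:
    """Diagnostics: r, r^2, residual SD, per-point back-calculated differences.

    The per-point difference is |x - (y - b)/a| in concentration units —
    the gap between the nominal level and the level recovered from its own
    fitted response.
    """
    resid = np.asarray(m.residuals)
    dof = max(m.n_points - 2, 1)
    back = (np.asarray(m.responses) - m.intercept) / m.slope
    diffs = np.abs(np.asarray(m.concentrations) - back)
    return {
        "r": m.r,
        "r_squared": m.r_squared,
        "residual_sd": float(np.sqrt((resid ** 2).sum() / dof)),
        "concentration_differences": diffs.tolist(),
    }


def predict_concentration(m: CalibrationModel, auc: float) -> float:
    """Inverse prediction x = (auc - intercept) / slope, % w/w.

    Values below zero (auc < intercept) are returned as-is; range checks
    against LOQ/linearity limits are the caller's concern.
    """
    if m.slope == 0:
        raise ZeroDivisionError("degenerate calibration model: zero slope")
    return (auc - m.intercept) / m.slope


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    """Load calibration levels from CSV: ``concentration,auc_rep1..repN``.

    A header line is optional; trailing empty cells are ignored so ragged
    replicate counts are allowed.
    """
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    if not pd.api.types.is_numeric_dtype(df.iloc[0]) and \
            pd.to_numeric(df.iloc[0], errors="coerce").isna().any():
        df = df.iloc[1:]
    points = []
    for _, row in df.iterrows():
        vals = pd.to_numeric(row, errors="coerce").dropna().tolist()
        if len(vals) < 2:
            raise ValueError(f"calibration row needs a concentration and >=1 AUC: {row.tolist()}")
        points.append(CalibrationPoint(vals[0], tuple(vals[1:])))
    return points
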