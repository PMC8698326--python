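"""Analytical-method validation math: weighted quadratic calibration and
precision/accuracy acceptance checks.

Calibration models the analyte-to-internal-standard peak-area ratio as a
quadratic in nominal concentration, fitted by 1/x weighted least squares
(the weighting counters the proportional variance typical of LC-MS/MS
responses).  A curve is acceptable when its (weighted) coefficient of
determination reaches 0.99.  Method validation follows the forensic
toxicology convention: relative bias and intra-/inter-day precision must
stay below 25% at the LLOQ and 20% elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "LevelValidation",
    "ValidationReport",
    "fit_calibration",
    "back_calculate",
    "validate_method",
]

R2_ACCEPT = 0.99
CV_LIMIT_LLOQ = 25.0  # percent
CV_LIMIT_OTHER = 20.0


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    points: tuple[tuple[float, float], ...]  # (nominal ng/mg, response ratio)
    coefficients: tuple[float, float, float]  # (a, b, c): y = a x^2 + b x + c
    r2: float

    @property
    def acceptable(self) -> bool:
        return self.r2 >= R2_ACCEPT

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        a, b, c = self.coefficients
        return a * np.square(x) + b * np.asarray(x, dtype=float) + c


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    weighting: str = "1/x",
) -> CalibrationCurve:
    """Fit y = a x^2 + b x + c by least squares with weights 1/x.

    Requires >= 5 distinct positive nominal concentrations.  The weighted
    normal equations are solved directly; r^2 uses weighted residual and
    total sums of squares about the weighted mean.  ``weighting="none"``
    gives the ordinary (unweighted) quadratic fit.
    """
    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.any(xs <= 0):
        raise ValueError("nominal concentrations must be > 0 (1/x weights)")
    if len(np.unique(xs)) < 5:
        raise ValueError("need >= 5 distinct nominal concentrations")
    if weighting == "1/x":
        w = 1.0 / xs
    elif weighting == "none":
        w = np.ones_like(xs)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    X = np.column_stack([xs**2, xs, np.ones_like(xs)])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
    yhat = X @ beta
    ybar_w = np.sum(w * ys) / np.sum(w)
    ss_res = float(np.sum(w * (ys - yhat) ** 2))
    ss_tot = float(np.sum(w * (ys - ybar_w) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        analyte=analyte,
        points=tuple(pts),
        coefficients=(float(beta[0]), float(beta[1]), float(beta[2])),
        r2=float(r2),
    )


def back_calculate(curve: CalibrationCurve, response: float) -> float:
    """Invert the calibration: concentration whose predicted response equals
    ``response``, taking the root inside (or nearest) the calibrated range."""
    a, b, c = curve.coefficients
    lo = min(x for x, _ in curve.points)
    hi = max(x for x, _ in curve.points)
    if abs(a) < 1e-15:
        if b == 0:
            raise ValueError("degenerate calibration: flat curve")
        return (response - c) / b
    disc = b * b - 4 * a * (c - response)
    if disc < 0:
        raise ValueError("response outside the calibration curve's range")
    roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1.0, -1.0)]
    inside = [r for r in roots if lo - 1e-9 <= r <= hi + 1e-9]
    if inside:
        return float(min(inside, key=lambda r: abs(r - (lo + hi) / 2)))
    return float(min(roots, key=lambda r: min(abs(r - lo), abs(r - hi))))


@dataclass(frozen=True)
class LevelValidation:
    level: float  # nominal ng/mg
    is_lloq: bool
    relative_bias_pct: float
    intra_day_cv_pct: float
    inter_day_cv_pct: float
    passed: bool


@dataclass(frozen=True)
class ValidationReport:
    analyte: str
    levels: tuple[LevelValidation, ...]
    lloq_estimate: float | None  # lowest level passing the 25% rule
    passed: bool


def _rsd(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return float("inf") if values.std(ddof=1) > 0 else 0.0
    return 100.0 * values.std(ddof=1) / abs(m)


def validate_method(
    replicates: pd.DataFrame,
    curve: CalibrationCurve,
    lloq_level: float | None = None,
) -> ValidationReport:
    """Accuracy/precision validation from a level x day x replicate table.

    ``replicates`` needs columns level_ng_mg, day, replicate, response.
    Responses are back-calculated through ``curve``.  Per level: relative
    bias = 100 * (mean back-calculated - nominal) / nominal; intra-day CV
    pools within-day RSDs (root-mean-square across days); inter-day CV is
    the RSD of day means.  A level passes when |bias| and both CVs stay
    under 25% at the LLOQ and 20% elsewhere.  The LLOQ estimate is the
    lowest level meeting the 25% rule.
    """
    required = {"level_ng_mg", "day", "replicate", "response"}
    missing = required - set(replicates.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    levels = sorted(replicates["level_ng_mg"].unique())
    if len(levels) < 3:
        raise ValueError(f"need >= 3 levels, got {len(levels)}")
    if lloq_level is None:
        lloq_level = levels[0]
    out: list[LevelValidation] = []
    lloq_estimate: float | None = None
    for level in levels:
        sub = replicates[replicates["level_ng_mg"] == level]
        days = sub["day"].unique()
        if len(days) < 2 or (sub.groupby("day").size() < 2).any():
            raise ValueError(f"level {level}: need >= 2 days with >= 2 replicates")
        back = sub["response"].map(lambda r: back_calculate(curve, r))
        bias = 100.0 * (back.mean() - level) / level
        within = [
            _rsd(back[sub["day"] == d].to_numpy(dtype=float)) for d in days
        ]
        intra = float(np.sqrt(np.mean(np.square(within))))
        day_means = back.groupby(sub["day"]).mean().to_numpy(dtype=float)
        inter = _rsd(day_means)
        limit = CV_LIMIT_LLOQ if level == lloq_level else CV_LIMIT_OTHER
        passed = abs(bias) < limit and intra < limit and inter < limit
        meets_lloq_rule = (
            abs(bias) < CV_LIMIT_LLOQ and intra < CV_LIMIT_LLOQ and inter < CV_LIMIT_LLOQ
        )
        if meets_lloq_rule and lloq_estimate is None:
            lloq_estimate = float(level)
        out.append(
            LevelValidation(
                level=float(level),
                is_lloq=level == lloq_level,
                relative_bias_pct=float(bias),
                intra_day_cv_pct=intra,
                inter_day_cv_pct=float(inter),
                passed=passed,
            )
        )
    return ValidationReport(
        analyte=curve.analyte,
        levels=tuple(out),
        lloq_estimate=lloq_estimate,
        passed=all(lv.passed for lv in out),
    )
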