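"""Era-stratified descriptive statistics, contingency tests, and logistic
regression of consumption on time/status.

Descriptive summaries (medians, ranges) are computed over detected values
only; regression design matrices set ND to 0.  The era split is the binary
1800 AD periodization from :func:`paleoxeno.cohort.era_of`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .classify import methylxanthine_pattern
from .cohort import ANALYTES, Cohort, era_of

__all__ = [
    "DetectionSummary",
    "ContingencyTest",
    "LogisticFit",
    "detection_summary",
    "combo_counts",
    "combo_era_test",
    "fit_logistic",
]

Era = Literal["before_1800", "after_1800"]
Contrast = Literal["tb_only_vs_rest", "tbcaf_vs_all3", "all3_vs_none"]

_PATTERN_KEYS = ("all_three", "tb_caf", "tb_only", "none")


@dataclass(frozen=True)
class DetectionSummary:
    detection_counts: dict[str, int]
    n_individuals: int
    n_with_any_methylxanthine: int
    combo_counts: dict[str, dict[str, int]]  # era -> pattern -> count
    era_sizes: dict[str, int]
    #: era -> analyte -> (n_detected, median, min, max) or None if none detected
    medians: dict[str, dict[str, tuple[int, float, float, float] | None]]


@dataclass(frozen=True)
class ContingencyTest:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    outcome: str
    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    converged: bool
    separation_suspected: bool
    n_obs: int
    warnings: tuple[str, ...] = field(default=())

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "z_value": self.zvalues,
                "p_value": self.pvalues,
            }
        )


def _pattern_key(pattern: tuple[bool, bool, bool]) -> str | None:
    if pattern == (True, True, True):
        return "all_three"
    if pattern == (True, True, False):
        return "tb_caf"
    if pattern == (True, False, False):
        return "tb_only"
    if pattern == (False, False, False):
        return "none"
    return None  # other mixed patterns are not tracked as named combos


def combo_counts(cohort: Cohort, era: Era) -> dict[str, int]:
    """Counts of named methylxanthine detection patterns within one era."""
    counts = dict.fromkeys(_PATTERN_KEYS, 0)
    for ind in cohort:
        if era_of(ind) != era:
            continue
        key = _pattern_key(methylxanthine_pattern(ind))
        if key is not None:
            counts[key] += 1
    return counts


def detection_summary(cohort: Cohort) -> DetectionSummary:
    """Detection counts, per-era pattern counts, and detected-only medians."""
    det_counts = {
        a: sum(1 for ind in cohort if not ind.conc(a).is_nd) for a in ANALYTES
    }
    n_any_mx = sum(
        1 for ind in cohort if any(methylxanthine_pattern(ind))
    )
    eras = [era_of(ind) for ind in cohort]
    era_sizes = {e: eras.count(e) for e in ("before_1800", "after_1800")}
    combos = {
        e: combo_counts(cohort, e) for e in ("before_1800", "after_1800")
    }
    medians: dict[str, dict[str, tuple[int, float, float, float] | None]] = {}
    for e in ("before_1800", "after_1800"):
        medians[e] = {}
        for a in ANALYTES:
            vals = [
                ind.conc(a).value
                for ind, era in zip(cohort, eras)
                if era == e and not ind.conc(a).is_nd
            ]
            if vals:
                arr = np.asarray(vals, dtype=float)
                medians[e][a] = (
                    len(arr),
                    float(np.median(arr)),
                    float(arr.min()),
                    float(arr.max()),
                )
            else:
                medians[e][a] = None
    return DetectionSummary(
        detection_counts=det_counts,
        n_individuals=len(cohort),
        n_with_any_methylxanthine=n_any_mx,
        combo_counts=combos,
        era_sizes=era_sizes,
        medians=medians,
    )


def _contrast_membership(
    pattern: tuple[bool, bool, bool], contrast: Contrast
) -> bool | None:
    """Return True/False for the two arms of a contrast, None if the
    individual is outside both arms."""
    key = _pattern_key(pattern)
    if contrast == "tb_only_vs_rest":
        # theobromine alone versus every other *detected* pattern; the
        # no-detection group has its own contrast and is excluded here
        # (this reading reproduces the published flat-over-time result)
        if not any(pattern):
            return None
        return key == "tb_only"
    if contrast == "tbcaf_vs_all3":
        if key == "tb_caf":
            return True
        if key == "all_three":
            return False
        return None
    if contrast == "all3_vs_none":
        if key == "all_three":
            return True
        if key == "none":
            return False
        return None
    raise ValueError(f"unknown contrast {contrast!r}")


def combo_era_test(cohort: Cohort, contrast: Contrast) -> ContingencyTest:
    """Two-sided Fisher exact test of a pattern contrast against era.

    The 2x2 table is era (before/after 1800) by contrast membership; the
    p-value sums hypergeometric probabilities no larger than the observed
    table's, the classic two-sided Fisher convention.
    """
    table = np.zeros((2, 2), dtype=int)
    for ind in cohort:
        member = _contrast_membership(methylxanthine_pattern(ind), contrast)
        if member is None:
            continue
        i = 0 if era_of(ind) == "before_1800" else 1
        table[i, 0 if member else 1] += 1
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError(f"empty margin for contrast {contrast!r}: {table.tolist()}")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return ContingencyTest(
        table=tuple(map(tuple, table.tolist())),  # type: ignore[arg-type]
        odds_ratio=float(odds),
        p_value=float(p),
    )


def _design_matrix(
    cohort: Cohort, predictors: Sequence[str]
) -> pd.DataFrame:
    frame = cohort.to_frame()
    X = frame[list(predictors)].fillna(0.0)
    X.index = frame["sample_id"]
    return X


def fit_logistic(
    cohort: Cohort,
    outcome: Literal["era_after_1800", "shaman"] = "era_after_1800",
    predictors: Sequence[str] = ("theophylline", "theobromine", "caffeine"),
    nd_policy: Literal["zero"] = "zero",
    exclude_outliers: bool = False,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression with Wald inference.

    Outcomes: ``era_after_1800`` (1 for individuals dated after 1800) or
    ``shaman`` (suspected-shaman status).  Predictors are analyte
    concentrations with ND set to 0, in pg/mg.  Quasi-complete separation
    is flagged (fitted probabilities numerically at 0/1), never silenced.
    """
    if nd_policy != "zero":
        raise ValueError("logistic fits support nd_policy='zero' only")
    data = cohort.without_outliers() if exclude_outliers else cohort
    frame = data.to_frame()
    if outcome == "era_after_1800":
        y = pd.Series(
            [1 if era_of(ind) == "after_1800" else 0 for ind in data],
            index=frame["sample_id"],
            name="era_after_1800",
        )
    elif outcome == "shaman":
        y = pd.Series(
            frame["shaman"].astype(int).to_numpy(),
            index=frame["sample_id"],
            name="shaman",
        )
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    X = _design_matrix(data, predictors)
    zero_var = [c for c in X.columns if X[c].nunique() <= 1]
    if zero_var:
        raise ValueError(f"zero-variance predictor(s): {zero_var}")
    X = sm.add_constant(X)
    msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        model = sm.Logit(y, X)
        try:
            result = model.fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            # Newton fails on (quasi-)separated data; fall back to a
            # gradient method and surface the diagnosis instead of dying
            msgs.append(f"Newton fit failed ({exc}); refitted with BFGS")
            result = model.fit(disp=0, maxiter=500, method="bfgs")
        msgs.extend(str(w.message) for w in caught)
    fitted = np.asarray(result.predict(X), dtype=float)
    yv = y.to_numpy(dtype=float)
    # complete separation: the fit classifies every row with probability
    # numerically at its label; quasi-separation: single rows pinned at 0/1
    separation = bool(
        np.all(np.abs(yv - fitted) < 1e-4)
        or np.any(fitted < 1e-10)
        or np.any(fitted > 1 - 1e-10)
    )
    if separation:
        msgs.append("quasi-complete separation suspected: fitted probabilities at 0/1")
    return LogisticFit(
        outcome=outcome,
        predictors=tuple(predictors),
        params=result.params,
        bse=result.bse,
        zvalues=result.tvalues,
        pvalues=result.pvalues,
        converged=bool(result.mle_retvals.get("converged", True)),
        separation_suspected=separation,
        n_obs=int(result.nobs),
        warnings=tuple(msgs),
    )
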