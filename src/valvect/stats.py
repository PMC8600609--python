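"""The statistical battery used on cohorts and reproducibility tables.

Spearman rank correlation (undefined fibrocalcific ratios rank above all
finite values), the intraclass correlation ICC(2,1) — two-way random
effects, absolute agreement, single rater — with an F-based confidence
interval, and the peak-velocity linear model with a sex-by-score
interaction on a log2-transformed score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import StatsError
from .quantification import UNDEFINED_RATIO

ICC_MODEL = "two-way random, absolute agreement, single rater"


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = ICC_MODEL

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.icc <= 1.0 + 1e-9:
            raise StatsError(f"ICC out of [-1, 1]: {self.icc}")
        if self.ci_low > self.icc + 1e-9 or self.ci_high < self.icc - 1e-9:
            raise StatsError("confidence interval does not bracket the ICC")


@dataclass(frozen=True)
class RegressionResult:
    """OLS of peak velocity on age, female sex, log2(score) and the
    sex-by-score interaction."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    n: int

    def __post_init__(self) -> None:
        if self.adjusted_r2 > 1.0 + 1e-12:
            raise StatsError(f"adjusted R^2 > 1: {self.adjusted_r2}")


def _to_rankable(values) -> np.ndarray:
    """Map a value sequence to floats, sending the undefined-ratio sentinel
    above every finite value (+inf ranks highest under average ranks)."""
    out = np.empty(len(values), dtype=np.float64)
    for i, v in enumerate(values):
        out[i] = np.inf if v is UNDEFINED_RATIO else float(v)
    return out


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Either argument may contain `UNDEFINED_RATIO` sentinels (valves with
    no calcium), which enter the ranking above all finite values.
    """
    xv, yv = _to_rankable(x), _to_rankable(y)
    if xv.size != yv.size or xv.size < 3:
        raise StatsError("spearman needs two equal-length sequences of n >= 3")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise StatsError("spearman undefined for a constant input")
    rho, p = sps.spearmanr(xv, yv)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=int(xv.size))


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_subjects, k_raters) table with no missing cells.
    The point estimate comes from the two-way ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    and the confidence interval is the standard F-based one (Shrout-Fleiss
    / McGraw-Wong), with the rater-by-subject interaction as error.
    """
    r = np.asarray(ratings, dtype=np.float64)
    if r.ndim != 2:
        raise StatsError("ratings must be a 2-D subjects x raters table")
    n, k = r.shape
    if k < 2 or n < 5:
        raise StatsError(f"need >=2 raters and >=5 subjects, got {k} and {n}")
    if np.isnan(r).any():
        raise StatsError("ratings contain missing cells; no imputation is done")

    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((r - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        # all variance components zero (identical constant table)
        raise StatsError("ratings table has no variance; ICC undefined")
    icc = (msr - mse) / denom

    if mse <= 0 and msc <= 0:  # perfect agreement: degenerate CI
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0)

    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    fj = msc / mse
    v = (a * fj + b) ** 2 / (a**2 * fj**2 / (k - 1.0) + b**2 / (n - 1.0))
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (
        n * (msr - f_l * mse)
        / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    )
    return ICCResult(
        icc=float(icc),
        ci_low=float(min(lower, icc)),
        ci_high=float(max(upper, icc)),
    )


def velocity_regression(
    cohort: pd.DataFrame,
    score_column: str,
    velocity_column: str = "peak_velocity_ms",
    sex_column: str = "sex",
    age_column: str = "age",
) -> RegressionResult:
    """OLS of peak velocity on age + female sex + log2(score) + interaction.

    The score is log2-transformed, so every value must be strictly
    positive; offending rows are reported, not dropped silently.
    """
    if len(cohort) <= 10:
        raise StatsError("velocity regression needs n > 10")
    score = np.asarray(cohort[score_column], dtype=np.float64)
    bad = np.flatnonzero(~(score > 0))
    if bad.size:
        raise StatsError(
            f"non-positive {score_column} values at rows {bad.tolist()[:20]}; "
            "log2 transform undefined"
        )
    female = (cohort[sex_column].astype(str).str.upper() == "F").astype(float)
    log2s = np.log2(score)
    X = pd.DataFrame(
        {
            "age": np.asarray(cohort[age_column], dtype=np.float64),
            "female": female.to_numpy(),
            "log2_score": log2s,
            "female_x_log2_score": female.to_numpy() * log2s,
        }
    )
    X = sm.add_constant(X)
    fit = sm.OLS(np.asarray(cohort[velocity_column], dtype=np.float64), X).fit()
    return RegressionResult(
        coefficients=dict(fit.params),
        std_errors=dict(fit.bse),
        p_values=dict(fit.pvalues),
        adjusted_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )
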