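"""Inferential layer: Wilson intervals, 2×2 chi-square, small-n OLS.

Mislabeling rates are binomial proportions with modest n, so confidence
intervals use Wilson's score method.  Rates are compared between strata
(cities, vendor types, name sources) with Pearson's chi-square on 2×2
tables without continuity correction, and mislabeling percentages are
regressed on availability/demand proxies with ordinary least squares
(optionally on log10-transformed predictors, as for landings tonnage that
spans orders of magnitude).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .labeling import CallStatus

__all__ = [
    "RateEstimate",
    "Chi2Result",
    "RegressionResult",
    "wilson_ci",
    "chi2_2x2",
    "ols_fit",
    "stratified_rates",
    "availability_regression",
]


@dataclass(frozen=True)
class RateEstimate:
    """A binomial rate (percent) with its Wilson score interval."""

    k: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.ci_low <= self.rate <= self.ci_high <= 100.0):
            raise ValueError("interval must satisfy 0 <= low <= rate <= high <= 100")


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    df: int = 1

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be non-negative")


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS y ~ x with the F test of the slope (df 1, n−2)."""

    predictor: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    transform: str = "none"

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> RateEstimate:
    """Wilson score interval for k successes in n trials, on the percent scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    rate = 100.0 * k / n
    # guard against float dust at the k=0 / k=n boundaries
    ci_low = min(max(0.0, 100.0 * float(low)), rate)
    ci_high = max(min(100.0, 100.0 * float(high)), rate)
    return RateEstimate(k=k, n=n, rate=rate, ci_low=ci_low, ci_high=ci_high, alpha=alpha)


def chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square on a 2×2 table, without continuity correction."""
    observed = np.asarray(table, dtype=float)
    if observed.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    result = sps.chi2_contingency(observed, correction=False)
    return Chi2Result(
        statistic=float(result.statistic), p_value=float(result.pvalue),
        observed=observed, expected=np.asarray(result.expected_freq),
    )


def ols_fit(x, y, transform: str = "none", predictor: str = "x") -> RegressionResult:
    """OLS of y on x; R² is the squared Pearson correlation, p from F(1, n−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if transform == "log10_x":
        if (x <= 0).any():
            raise ValueError("log10 transform requires all x > 0")
        x = np.log10(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    df = n - 2
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 / (1.0 - r2) * df
        p = float(sps.f.sf(f_stat, 1, df))
    return RegressionResult(
        predictor=predictor, n=n, slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=min(r2, 1.0),
        f_statistic=f_stat, p_value=p, transform=transform,
    )


_CALLED = (CallStatus.CORRECT.value, CallStatus.MISLABELED.value)
_STRATA = ("city", "vendor_type", "name_source", "commercial_name")


def stratified_rates(
    calls: pd.DataFrame,
    stratum: str,
    alpha: float = 0.05,
) -> tuple[dict[str, RateEstimate], pd.DataFrame]:
    """Per-stratum mislabeling rates and all pairwise 2×2 chi-squares.

    Excluded calls are omitted from denominators; strata with no called
    samples are dropped.  The pairwise frame has columns ``a, b, statistic,
    p_value``; a single stratum yields an empty frame.
    """
    if stratum not in _STRATA:
        raise ValueError(f"stratum must be one of {_STRATA}")
    called = calls[calls["status"].isin(_CALLED)]
    estimates: dict[str, RateEstimate] = {}
    counts: dict[str, tuple[int, int]] = {}
    for value, sub in called.groupby(stratum):
        n = len(sub)
        if n == 0:
            continue
        k = int((sub["status"] == CallStatus.MISLABELED.value).sum())
        estimates[str(value)] = wilson_ci(k, n, alpha=alpha)
        counts[str(value)] = (k, n - k)
    rows = []
    for a, b in itertools.combinations(sorted(counts), 2):
        try:
            res = chi2_2x2([counts[a], counts[b]])
        except ValueError:
            continue  # a zero margin (e.g. no mislabels anywhere) is untestable
        rows.append({"a": a, "b": b, "statistic": res.statistic, "p_value": res.p_value})
    return estimates, pd.DataFrame(rows, columns=["a", "b", "statistic", "p_value"])


def availability_regression(
    landings: Mapping[str, float] | pd.DataFrame,
    audits,
) -> RegressionResult:
    """Mislabeling percentage regressed on log10 landings/imports tonnage.

    ``landings`` maps commercial name → tons per year (or a DataFrame with
    ``commercial_name`` and ``tons``); ``audits`` is a sequence of
    :class:`fishaudit.audit.NameAudit`.  At least three names must be shared
    and all tonnages positive.
    """
    if isinstance(landings, pd.DataFrame):
        landings = dict(zip(landings["commercial_name"], landings["tons"]))
    by_name = {a.commercial_name: a for a in audits}
    shared = sorted(set(landings) & set(by_name))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 commercial names shared between landings and audits, got {len(shared)}"
        )
    tons = np.array([landings[n] for n in shared], dtype=float)
    if (tons <= 0).any():
        raise ValueError("tonnage must be positive for the log transform")
    rates = np.array([by_name[n].mislabeling_percentage for n in shared])
    return ols_fit(tons, rates, transform="log10_x", predictor="log10_tons")
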