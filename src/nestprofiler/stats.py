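"""Survival and nonparametric statistics for density-stratified cohorts.

Thin, contract-checked wrappers around lifelines (Kaplan-Meier, log-rank,
Cox proportional hazards with Efron tie handling) and scipy/sklearn
(Spearman, Wilcoxon signed-rank, Kruskal-Wallis, ROC/Youden cutoffs),
plus the cutoff rules used to dichotomize density features: cohort mean,
median, an externally fixed value (e.g. a discovery-cohort cutoff carried
into a validation cohort), or the ROC point maximizing Youden's J against
the event label. The high group includes the cutoff value (>=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import ConvergenceWarning
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "CoxResult",
    "cox_fit",
    "spearman_matrix",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "CutoffRule",
    "DichotomizeResult",
    "dichotomize",
    "two_marker_strata",
]


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier product-limit curve.

    ``times`` starts at 0 with ``survival`` 1.0; the curve is piecewise
    constant and non-increasing. ``at_risk`` is the risk-set size just
    before each time. ``median_time`` is inf while S stays above 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_time: float

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, float)
        if s.size == 0 or not np.isclose(s[0], 1.0):
            raise ValueError("survival must start at 1.0")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate; censored times shrink the risk set stepless."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("no survival records")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    event_table = kmf.event_table
    at_risk = event_table["at_risk"].reindex(sf.index).to_numpy(float)
    return KMCurve(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        at_risk=at_risk,
        median_time=float(kmf.median_survival_time_),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 df); returns (statistic, p)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank test undefined with zero events overall")
    res = _lifelines_logrank(
        times_a, times_b, event_observed_A=events_a, event_observed_B=events_b
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit: per-covariate HR, Wald 95% CI and p."""

    summary: pd.DataFrame  # index: covariate; hazard_ratio, ci_low, ci_high, p
    converged: bool
    ties_method: str

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox partial-likelihood fit (Efron tie correction) via lifelines.

    Requires >= 2 events and non-constant covariates. Monotone-likelihood /
    separation problems are reported through ``converged=False`` rather than
    as unstable hazard ratios.
    """
    if int(np.asarray(cohort[event_col], bool).sum()) < 2:
        raise ValueError("Cox fit requires at least 2 events")
    for cov in covariates:
        if cohort[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    frame = cohort[covariates + [duration_col, event_col]].astype(float)
    fitter = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            fitter.fit(frame, duration_col=duration_col, event_col=event_col)
        except (ConvergenceWarning, ConvergenceError, Exception) as exc:
            if isinstance(exc, (ConvergenceWarning, ConvergenceError)):
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fitter.fit(
                        frame, duration_col=duration_col, event_col=event_col
                    )
            else:
                raise
    summary = pd.DataFrame(
        {
            "hazard_ratio": fitter.summary["exp(coef)"],
            "ci_low": fitter.summary["exp(coef) lower 95%"],
            "ci_high": fitter.summary["exp(coef) upper 95%"],
            "p": fitter.summary["p"],
        }
    )
    return CoxResult(summary=summary, converged=converged, ties_method="efron")


def spearman_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix with average-rank ties.

    Constant features have undefined correlations and are reported as NaN
    (including their diagonal); other diagonal entries are exactly 1.
    """
    if len(features) < 3:
        raise ValueError("Spearman matrix requires >= 3 patients")
    numeric = features.select_dtypes(include=[np.number])
    corr = numeric.corr(method="spearman")
    constant = [c for c in numeric.columns if numeric[c].nunique() <= 1]
    for c in numeric.columns:
        corr.loc[c, c] = np.nan if c in constant else 1.0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    for c in set(numeric.columns) - set(constant):
        corr.loc[c, c] = 1.0
    return corr


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; the p-value is exact for n <= 25 pairs and
    a continuity-corrected normal approximation beyond that.
    """
    a, b = np.asarray(paired_a, float), np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    n = int((diffs != 0).sum())
    if n == 0:
        raise ValueError("degenerate: all paired differences are zero")
    if n < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 5:
        raise ValueError("need total n >= 5")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        raise ValueError("degenerate: all values identical")
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CutoffRule:
    """How to dichotomize a density feature: mean, median, a fixed value
    (e.g. 43.1 cells/mm^2 carried from a discovery cohort), or the ROC point
    maximizing Youden's J against the event label."""

    kind: str
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "median", "fixed", "roc_youden"):
            raise ValueError(f"unknown cutoff kind {self.kind!r}")
        if (self.kind == "fixed") != (self.fixed_value is not None):
            raise ValueError("fixed_value present iff kind='fixed'")


@dataclass(frozen=True)
class DichotomizeResult:
    high: np.ndarray  # boolean, value >= cutoff
    cutoff: float


def dichotomize(
    values, rule: CutoffRule, events=None
) -> DichotomizeResult:
    """Split patients into high (>= cutoff) and low (< cutoff) groups."""
    values = np.asarray(values, float)
    if rule.kind == "mean":
        cutoff = float(values.mean())
    elif rule.kind == "median":
        cutoff = float(np.median(values))
    elif rule.kind == "fixed":
        cutoff = float(rule.fixed_value)
    else:  # roc_youden
        if events is None:
            raise ValueError("roc_youden rule requires event labels")
        events = np.asarray(events, bool)
        if events.all() or not events.any():
            raise ValueError("ROC undefined with a single-class event label")
        fpr, tpr, thresholds = roc_curve(events, values)
        finite = np.isfinite(thresholds)
        j = tpr[finite] - fpr[finite]
        cutoff = float(thresholds[finite][int(np.argmax(j))])
    return DichotomizeResult(high=values >= cutoff, cutoff=cutoff)


def two_marker_strata(
    cohort: pd.DataFrame,
    feature_a: str,
    rule_a: CutoffRule,
    feature_b: str,
    rule_b: CutoffRule,
    event_col: str = "event",
) -> tuple[np.ndarray, dict[str, float]]:
    """Joint stratification by two density features.

    Returns labels ``both_high`` (high under both rules) vs ``other``,
    plus the two cutoffs used; downstream KM / log-rank compares the strata.
    """
    events = cohort[event_col].to_numpy(bool) if event_col in cohort else None
    res_a = dichotomize(cohort[feature_a].to_numpy(float), rule_a, events)
    res_b = dichotomize(cohort[feature_b].to_numpy(float), rule_b, events)
    labels = np.where(res_a.high & res_b.high, "both_high", "other")
    return labels, {feature_a: res_a.cutoff, feature_b: res_b.cutoff}
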