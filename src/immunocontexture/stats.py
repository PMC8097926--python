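"""Statistical layer: rank tests, correlations and survival analysis.

The cohort-level statistics used throughout the pipeline are the classical
small-cohort toolkit: two-tailed Mann-Whitney between patient groups,
Spearman rank correlation with a Fisher-z confidence interval, Kaplan-Meier
survival curves with median-split stratification, the log-rank (Mantel-Cox)
test, and univariate Cox proportional-hazards hazard ratios with Wald 95%
confidence intervals. No multiple-testing correction is applied anywhere;
p-values are reported raw.

Implementation notes
--------------------
* Mann-Whitney switches to the exact two-sided null distribution when
  n1 + n2 <= 12 and the pooled values carry no ties (at most C(12,6)=924
  arrangements, fully deterministic); otherwise the normal approximation
  with tie and continuity correction is used.
* The Spearman CI uses the Fisher z-transform with variance 1.06/(n-3),
  the standard adjustment for rank correlation.
* Kaplan-Meier / log-rank / Cox go through lifelines; Cox uses Efron tie
  handling, which behaves well under the heavy ties that median-split
  groupings produce. The Kaplan-Meier median is the smallest time with
  S(t) <= 0.5 and is explicitly encoded as undefined when never reached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_mv_logrank
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "SurvivalRecord",
    "GroupComparisonResult",
    "CorrelationResult",
    "KaplanMeierCurve",
    "LogrankResult",
    "CoxResult",
    "mann_whitney_test",
    "spearman_correlation",
    "kaplan_meier",
    "logrank_test",
    "multigroup_logrank_test",
    "cox_hazard_ratio",
]


@dataclass
class SurvivalRecord:
    """Per-patient outcome: time in months from metastatic diagnosis, death flag."""

    patient_id: str
    time: float
    event: bool
    groups: dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValidationError(f"patient {self.patient_id}: non-positive survival time")


@dataclass
class GroupComparisonResult:
    statistic: float  # Mann-Whitney U for the first sample
    p_two_sided: float
    n1: int
    n2: int
    method: str  # exact | normal-approximation


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p: float = float("nan")
    undefined: bool = False


@dataclass
class KaplanMeierCurve:
    times: np.ndarray  # event-time grid, starting at 0
    survival: np.ndarray  # S(t), starts at 1, non-increasing
    median: float | None  # None when S never reaches 0.5
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass
class LogrankResult:
    chi2: float
    p: float
    n_events: int
    undefined: bool = False


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_hr: float
    se_log_hr: float
    n: int
    n_events: int
    separation: bool = False  # unbounded likelihood; CI reported unbounded


def mann_whitney_test(x: Sequence[float], y: Sequence[float]) -> GroupComparisonResult:
    """Two-tailed Mann-Whitney U test with midranks for ties.

    Exact p by full enumeration of the null distribution when the pooled
    sample is small (n1+n2 <= 12) and tie-free; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_test: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    use_exact = (x.size + y.size) <= 12 and no_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = min(float(res.pvalue), 1.0)
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p_two_sided=p,
        n1=int(x.size),
        n2=int(y.size),
        method="exact" if use_exact else "normal-approximation",
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a 95% Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("spearman_correlation: unequal sample sizes")
    n = int(x.size)
    if n < 3:
        raise ValidationError("spearman_correlation: need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), n, undefined=True)
    r, p = sps.spearmanr(x, y)
    r = float(r)
    ci_low = ci_high = float("nan")
    if n >= 4 and abs(r) < 1.0:
        z = math.atanh(r)
        se = math.sqrt(1.06 / (n - 3))
        ci_low = math.tanh(z - 1.959963984540054 * se)
        ci_high = math.tanh(z + 1.959963984540054 * se)
    elif n >= 4:
        ci_low = ci_high = r  # degenerate perfect correlation
    return CorrelationResult(r, ci_low, ci_high, n, p=float(p))


def _as_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    for r in records:
        r.validate()
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([int(r.event) for r in records], dtype=int)
    return t, e


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Product-limit survival estimate; events precede censorings at ties."""
    if not records:
        raise ValidationError("kaplan_meier: need at least one record")
    t, e = _as_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return KaplanMeierCurve(times, surv, median, n=len(records), n_events=int(e.sum()))


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank (Mantel-Cox) test, chi-square with 1 df."""
    if not group_a or not group_b:
        raise ValidationError("logrank_test: both groups must be non-empty")
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    n_events = int(ea.sum() + eb.sum())
    if n_events == 0:
        return LogrankResult(float("nan"), float("nan"), 0, undefined=True)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(float(res.test_statistic), float(res.p_value), n_events)


def multigroup_logrank_test(
    records: Sequence[SurvivalRecord], labels: Sequence[object]
) -> LogrankResult:
    """k-group log-rank test (k-1 df), used for the three Immunoscore strata."""
    t, e = _as_arrays(records)
    n_events = int(e.sum())
    if n_events == 0:
        return LogrankResult(float("nan"), float("nan"), 0, undefined=True)
    res = _ll_mv_logrank(t, np.asarray(labels, dtype=object), e)
    return LogrankResult(float(res.test_statistic), float(res.p_value), n_events)


def cox_hazard_ratio(
    records: Sequence[SurvivalRecord], covariate: Sequence[float]
) -> CoxResult:
    """Univariate Cox PH hazard ratio for a binary (or numeric) covariate.

    The HR is reported for a unit increase of the covariate (i.e. for the
    level coded 1 versus 0). Efron tie handling; Wald 95% CI on the log
    scale. Complete separation is flagged and the CI reported unbounded.
    """
    t, e = _as_arrays(records)
    cov = np.asarray(covariate, dtype=float)
    if np.unique(cov).size < 2:
        raise ValidationError("cox_hazard_ratio: covariate must take at least two values")
    if int(e.sum()) < 2:
        raise ValidationError("cox_hazard_ratio: need at least two events")
    df = pd.DataFrame({"time": t, "event": e, "x": cov})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult(
            hr=float("nan"),
            ci_low=0.0,
            ci_high=float("inf"),
            p=float("nan"),
            log_hr=float("nan"),
            se_log_hr=float("inf"),
            n=len(records),
            n_events=int(e.sum()),
            separation=True,
        )
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    separation = not math.isfinite(se) or se > 50 or abs(beta) > 50
    return CoxResult(
        hr=math.exp(beta),
        ci_low=0.0 if separation else math.exp(beta - 1.959963984540054 * se),
        ci_high=float("inf") if separation else math.exp(beta + 1.959963984540054 * se),
        p=p,
        log_hr=beta,
        se_log_hr=se,
        n=len(records),
        n_events=int(e.sum()),
        separation=separation,
    )
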