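"""Derived prognostic constructions: ratios, median dichotomization, the
metastatic-melanoma Immunoscore variant, lymphoid/myeloid concordance groups
and RECIST disease-control classification.

The Immunoscore implemented here is the median-based variant used for small
metastatic cohorts: each of the four densities (CD3 and CD8, in tumor and in
stroma) is dichotomized at its own cohort median; the score is the number of
"high" indicators (0–4) and the class is I0 (score 0), I4 (score 4) or IntI
(1–3). The colorectal consensus percentile method is deliberately not
implemented.

Tie policy: a value exactly equal to the median is labeled **low**, so that
"high" always means strictly above the median. Zero denominators in ratios
yield an explicitly missing value rather than ±inf, since downstream rank
tests cannot order infinities meaningfully.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ValidationError

__all__ = [
    "DichotomizationRule",
    "ImmunoscoreResult",
    "ResponseLabel",
    "ratio_metric",
    "dichotomize_by_median",
    "compute_immunoscore",
    "concordance_group",
    "classify_response",
    "CONTROLLED",
    "PROGRESSIVE",
]

HIGH = "high"
LOW = "low"
CONTROLLED = "CD"  # disease control: CR, PR or SD
PROGRESSIVE = "PD"
RECIST_CODES = ("CR", "PR", "SD", "PD")
IMMUNOSCORE_CLASSES = ("I0", "IntI", "I4")


@dataclass(frozen=True)
class DichotomizationRule:
    """Record of one cohort median split (tie → low)."""

    metric: str
    median: float
    tie_policy: str = "low"


@dataclass
class ImmunoscoreResult:
    """Per-patient Immunoscore: four high/low indicators, their sum, the class."""

    patient_id: str
    indicators: dict[str, int]  # cd3_tumor, cd3_stroma, cd8_tumor, cd8_stroma -> 0/1
    score: int | None  # 0..4, None when any input metric is missing
    immunoscore_class: str | None  # I0 | IntI | I4


@dataclass(frozen=True)
class ResponseLabel:
    patient_id: str | None
    recist: str
    dcr_group: str  # CD | PD


def ratio_metric(numerator: float, denominator: float) -> float:
    """Ratio of two non-negative metrics; zero denominator → NaN (missing)."""
    if math.isnan(numerator) or math.isnan(denominator):
        return float("nan")
    if numerator < 0 or denominator < 0:
        raise ValidationError("ratio_metric: densities/percentages cannot be negative")
    if denominator == 0:
        return float("nan")
    return numerator / denominator


def dichotomize_by_median(
    values: Mapping[str, float], metric: str = ""
) -> tuple[dict[str, str | None], DichotomizationRule]:
    """Split patients into high/low at the cohort median of their values.

    value > median → high; value <= median → low; missing stays missing.
    The median is computed on the analyzed patients only, missing excluded.
    With all values identical every patient is low (degenerate; warned).
    """
    present = {k: v for k, v in values.items() if not math.isnan(v)}
    if len(present) < 2:
        raise ValidationError("dichotomize_by_median: need >= 2 non-missing values")
    vals = np.array(list(present.values()), dtype=float)
    median = float(np.median(vals))
    if np.unique(vals).size == 1:
        warnings.warn(
            f"dichotomize_by_median({metric or 'metric'}): all values identical; "
            "every patient labeled low",
            stacklevel=2,
        )
    labels: dict[str, str | None] = {}
    for k, v in values.items():
        if math.isnan(v):
            labels[k] = None
        else:
            labels[k] = HIGH if v > median else LOW
    return labels, DichotomizationRule(metric=metric, median=median)


def compute_immunoscore(
    cd3_tumor: Mapping[str, float],
    cd3_stroma: Mapping[str, float],
    cd8_tumor: Mapping[str, float],
    cd8_stroma: Mapping[str, float],
) -> dict[str, ImmunoscoreResult]:
    """Median-based Immunoscore over a cohort.

    Each of the four density vectors is dichotomized at its own cohort
    median; score = number of high indicators; class 0→I0, 4→I4, else IntI.
    Patients missing any of the four metrics get a missing (None) class.
    """
    metrics = {
        "cd3_tumor": cd3_tumor,
        "cd3_stroma": cd3_stroma,
        "cd8_tumor": cd8_tumor,
        "cd8_stroma": cd8_stroma,
    }
    cohort = set().union(*(m.keys() for m in metrics.values()))
    labels = {
        name: dichotomize_by_median(m, metric=name)[0] for name, m in metrics.items()
    }
    out: dict[str, ImmunoscoreResult] = {}
    for pid in sorted(cohort):
        indicators: dict[str, int] = {}
        missing = False
        for name in metrics:
            lab = labels[name].get(pid)
            if lab is None:
                missing = True
                break
            indicators[name] = 1 if lab == HIGH else 0
        if missing:
            out[pid] = ImmunoscoreResult(pid, {}, None, None)
            continue
        score = sum(indicators.values())
        cls = "I0" if score == 0 else ("I4" if score == 4 else "IntI")
        out[pid] = ImmunoscoreResult(pid, indicators, score, cls)
    return out


def concordance_group(cd3_label: str | None, cd68_label: str | None) -> str | None:
    """Concordant when intra-tumoral CD3 and CD68 high/low labels agree
    (high/high or low/low); discordant otherwise; missing propagates."""
    if cd3_label is None or cd68_label is None:
        return None
    for lab in (cd3_label, cd68_label):
        if lab not in (HIGH, LOW):
            raise ValidationError(f"unknown dichotomization label {lab!r}")
    return "concordant" if cd3_label == cd68_label else "discordant"


def classify_response(recist: str, patient_id: str | None = None) -> ResponseLabel:
    """RECIST 1.1 disease-control classification: CD iff CR, PR or SD."""
    if recist not in RECIST_CODES:
        raise ValidationError(
            f"unknown RECIST code {recist!r}; allowed: {list(RECIST_CODES)}"
        )
    group = CONTROLLED if recist in ("CR", "PR", "SD") else PROGRESSIVE
    return ResponseLabel(patient_id, recist, group)
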