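"""Ratios, median dichotomization, Immunoscore, concordance and DCR labels."""

import itertools
import math

import pytest

from immunocontexture import (
    ValidationError,
    classify_response,
    compute_immunoscore,
    concordance_group,
    dichotomize_by_median,
    ratio_metric,
)


def test_ratio_examples():
    assert ratio_metric(4.0, 2.0) == 2.0
    assert ratio_metric(0.0, 5.0) == 0.0
    assert math.isnan(ratio_metric(3.0, 0.0))  # missing, not infinity
    with pytest.raises(ValidationError):
        ratio_metric(-1.0, 2.0)


def test_dichotomize_even_n():
    labels, rule = dichotomize_by_median({"a": 1, "b": 2, "c": 3, "d": 4})
    assert rule.median == 2.5
    assert [labels[k] for k in "abcd"] == ["low", "low", "high", "high"]


def test_dichotomize_odd_n_sends_median_to_low():
    labels, rule = dichotomize_by_median({"a": 1, "b": 2, "c": 3})
    assert rule.median == 2
    assert [labels[k] for k in "abc"] == ["low", "low", "high"]


def test_dichotomize_degenerate_all_equal_warns_all_low():
    with pytest.warns(UserWarning, match="identical"):
        labels, _ = dichotomize_by_median({k: 5.0 for k in "abcd"})
    assert set(labels.values()) == {"low"}


def test_dichotomize_partition_invariant():
    labels, _ = dichotomize_by_median(
        {f"p{i}": v for i, v in enumerate([3, 1, 4, 1, 5, 9, 2, 6, 5])}
    )
    n_low = sum(1 for v in labels.values() if v == "low")
    n_high = sum(1 for v in labels.values() if v == "high")
    assert n_low >= n_high
    assert n_low + n_high == 9


def test_dichotomize_missing_stays_missing():
    labels, _ = dichotomize_by_median({"a": 1.0, "b": 2.0, "c": float("nan")})
    assert labels["c"] is None


def test_immunoscore_all_sixteen_indicator_combinations():
    """Exhaustive check of score = sum of indicators and the class mapping."""
    # construct a cohort whose four metrics produce every high/low combination
    # for the probe patient: background patients pin each median at 10
    for combo in itertools.product((0, 1), repeat=4):
        background = {f"b{i}": 10.0 for i in range(4)}
        metrics = []
        for ind in combo:
            m = dict(background)
            m["probe"] = 20.0 if ind else 5.0
            metrics.append(m)
        result = compute_immunoscore(*metrics)["probe"]
        expected_score = sum(combo)
        assert result.score == expected_score
        expected_class = {0: "I0", 4: "I4"}.get(expected_score, "IntI")
        assert result.immunoscore_class == expected_class
        assert result.score == sum(result.indicators.values())


def test_immunoscore_missing_metric_flags_patient():
    base = {"a": 1.0, "b": 2.0, "c": 3.0}
    broken = dict(base)
    broken["c"] = float("nan")
    result = compute_immunoscore(base, base, base, broken)
    assert result["c"].score is None
    assert result["c"].immunoscore_class is None
    assert result["a"].score is not None


@pytest.mark.parametrize(
    "cd3,cd68,expected",
    [
        ("high", "high", "concordant"),
        ("low", "low", "concordant"),
        ("high", "low", "discordant"),
        ("low", "high", "discordant"),
        (None, "high", None),
    ],
)
def test_concordance_groups(cd3, cd68, expected):
    assert concordance_group(cd3, cd68) == expected


def test_classify_response_rules():
    assert classify_response("SD").dcr_group == "CD"
    assert classify_response("CR").dcr_group == "CD"
    assert classify_response("PR").dcr_group == "CD"
    assert classify_response("PD").dcr_group == "PD"
    with pytest.raises(ValidationError, match="RECIST"):
        classify_response("XX")


def test_classify_response_is_idempotent_partition():
    cohort = ["PD"] * 7 + ["SD"] * 7 + ["PR"] * 6 + ["CR"] * 1
    labels = [classify_response(r) for r in cohort]
    # idempotent: re-classifying the recorded code gives the same label
    assert all(classify_response(l.recist).dcr_group == l.dcr_group for l in labels)
    cd = sum(1 for l in labels if l.dcr_group == "CD")
    pd_ = sum(1 for l in labels if l.dcr_group == "PD")
    assert (cd, pd_) == (14, 7)
    assert cd + pd_ == len(cohort)
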