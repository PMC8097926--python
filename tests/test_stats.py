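"""Rank tests, correlation and survival statistics against hand oracles."""

import math

import numpy as np
import pytest

from immunocontexture import (
    SurvivalRecord,
    ValidationError,
    cox_hazard_ratio,
    kaplan_meier,
    logrank_test,
    mann_whitney_test,
    spearman_correlation,
)


def recs(times, events, prefix="p"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mw_fully_separated_small_samples_exact():
    # all C(6,3)=20 labelings: 2 orderings as extreme -> p = 2/20
    res = mann_whitney_test([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.method == "exact"
    assert res.p_two_sided == pytest.approx(0.1)


def test_mw_two_vs_two_exact():
    # all C(4,2)=6 labelings, 2 extreme -> p = 1/3
    res = mann_whitney_test([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p_two_sided == pytest.approx(2.0 / 6.0)


def test_mw_identical_samples_p_is_one():
    res = mann_whitney_test([1, 2, 3], [1, 2, 3])
    assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)


def test_mw_u_statistics_sum_to_n1n2(rng):
    x = rng.normal(size=8)
    y = rng.normal(size=9)
    ux = mann_whitney_test(x, y).statistic
    uy = mann_whitney_test(y, x).statistic
    assert ux + uy == pytest.approx(8 * 9)


def test_mw_exact_p_invariant_under_monotone_transform():
    x, y = [1.0, 2.5, 3.0], [4.0, 5.5, 9.0]
    p1 = mann_whitney_test(x, y).p_two_sided
    p2 = mann_whitney_test([v**3 for v in x], [v**3 for v in y]).p_two_sided
    assert p1 == p2


def test_mw_switches_to_approximation_for_large_or_tied_samples():
    res = mann_whitney_test(list(range(10)), list(range(10, 20)))
    assert res.method == "normal-approximation"
    res = mann_whitney_test([1, 1, 2], [2, 3, 3])  # ties
    assert res.method == "normal-approximation"


def test_mw_empty_sample_rejected():
    with pytest.raises(ValidationError):
        mann_whitney_test([], [1.0])


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_monotone():
    assert spearman_correlation([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert spearman_correlation([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)


def test_spearman_hand_computed_four_points():
    # rank differences d = (0, 1, -1, 0): r = 1 - 6*2/(4*15) = 0.8
    res = spearman_correlation([1, 2, 3, 4], [1, 3, 2, 4])
    assert res.r == pytest.approx(0.8)
    assert res.ci_low <= res.r <= res.ci_high
    assert -1 <= res.ci_low and res.ci_high <= 1


def test_spearman_invariant_under_increasing_transform(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    r1 = spearman_correlation(x, y).r
    r2 = spearman_correlation(np.exp(x), 3 * y + 7).r
    assert r1 == pytest.approx(r2)


def test_spearman_constant_vector_flagged():
    res = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
    assert res.undefined


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_all_events_matches_hand_product_limit():
    curve = kaplan_meier(recs([1, 2, 3], [1, 1, 1]))
    assert curve.survival_at(1.0) == pytest.approx(2 / 3)
    assert curve.survival_at(2.0) == pytest.approx(1 / 3)
    assert curve.survival_at(3.0) == pytest.approx(0.0)
    assert curve.median == 2.0


def test_km_with_censoring_shrinks_risk_set():
    curve = kaplan_meier(recs([1, 2, 3], [1, 0, 1]))
    assert curve.survival_at(1.0) == pytest.approx(2 / 3)
    assert curve.survival_at(3.0) == pytest.approx(0.0)
    assert curve.median == 3.0


def test_km_all_censored_median_undefined():
    curve = kaplan_meier(recs([1, 2, 3], [0, 0, 0]))
    assert np.allclose(curve.survival, 1.0)
    assert curve.median is None


def test_km_without_censoring_equals_empirical_survival(rng):
    times = rng.exponential(10.0, size=40)
    curve = kaplan_meier(recs(times, np.ones(40)))
    for t in (1.0, 5.0, 12.0):
        empirical = np.mean(times > t)
        assert curve.survival_at(t) == pytest.approx(empirical)


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValidationError):
        kaplan_meier(recs([0.0, 1.0], [1, 1]))


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_hand_computed_four_patients():
    # A: events at 1,2; B: events at 3,4 -> chi2 = (7/6)^2/(17/36) = 49/17
    res = logrank_test(recs([1, 2], [1, 1], "a"), recs([3, 4], [1, 1], "b"))
    assert res.chi2 == pytest.approx(49.0 / 17.0, rel=1e-6)
    assert res.chi2 == pytest.approx(2.882, abs=0.001)


def test_logrank_identical_groups_null():
    g = recs([1, 2, 3, 4], [1, 1, 1, 1])
    res = logrank_test(g, recs([1, 2, 3, 4], [1, 1, 1, 1], "b"))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_no_events_flagged():
    res = logrank_test(recs([1, 2], [0, 0], "a"), recs([3], [0], "b"))
    assert res.undefined


def test_logrank_matches_cox_score_statistic_at_null(rng):
    """The log-rank chi-square equals the Cox partial-likelihood score test
    at beta=0 (hand-computed here with Breslow handling; no ties occur)."""
    n = 240
    times = rng.exponential(20.0, size=n)
    group = rng.integers(0, 2, size=n)
    events = np.ones(n, dtype=int)
    # hand-computed score statistic
    order = np.argsort(times)
    t_s, g_s = times[order], group[order]
    u = 0.0
    v = 0.0
    for i in range(n):
        at_risk = g_s[i:]
        p1 = at_risk.mean()
        u += g_s[i] - p1
        v += p1 * (1 - p1)
    score_chi2 = u * u / v
    res = logrank_test(
        recs(times[group == 1], events[group == 1], "a"),
        recs(times[group == 0], events[group == 0], "b"),
    )
    assert res.chi2 == pytest.approx(score_chi2, rel=0.05)


# ---------------------------------------------------------------------------
# Cox


def test_cox_identical_groups_hr_one():
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    events = [1, 1, 1, 1, 1, 1]
    res = cox_hazard_ratio(recs(times + times, events + events), [1] * 6 + [0] * 6)
    assert res.hr == pytest.approx(1.0, abs=1e-6)


def test_cox_label_swap_inverts_hr(rng):
    times = rng.exponential(10.0, size=30)
    events = rng.random(30) < 0.8
    cov = (rng.random(30) < 0.5).astype(float)
    r1 = cox_hazard_ratio(recs(times, events), cov)
    r2 = cox_hazard_ratio(recs(times, events), 1.0 - cov)
    assert r1.hr * r2.hr == pytest.approx(1.0, rel=1e-6)


def test_cox_complete_separation_flagged():
    # all group-1 events strictly before every group-0 time: unbounded beta
    g1 = recs([1, 2, 3, 4, 5], [1, 1, 1, 1, 1], "a")
    g0 = recs([10, 11, 12, 13, 14], [1, 1, 1, 1, 1], "b")
    res = cox_hazard_ratio(g1 + g0, [1] * 5 + [0] * 5)
    assert res.separation
    assert res.ci_high == math.inf
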