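"""Survival and rank statistics: closed-form fixtures, enumeration and
permutation oracles, monotone-invariance properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nestprofiler.simulate import CohortSimSpec, generate_cohort
from nestprofiler.stats import (
    CutoffRule,
    cox_fit,
    dichotomize,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    spearman_matrix,
    two_marker_strata,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_all_censored_flat_curve():
    curve = km_estimate([3.0, 5.0, 9.0], [False, False, False])
    assert np.allclose(curve.survival, 1.0)
    assert np.isinf(curve.median_time)


def test_km_two_events_closed_form():
    curve = km_estimate([1.0, 2.0], [True, True])
    lookup = dict(zip(curve.times, curve.survival))
    assert lookup[1.0] == pytest.approx(0.5)
    assert lookup[2.0] == pytest.approx(0.0)


def test_km_exponential_median(rng):
    lam = 0.05
    times = rng.exponential(1 / lam, 5000)
    curve = km_estimate(times, np.ones(5000, bool))
    assert abs(curve.median_time - np.log(2) / lam) / (np.log(2) / lam) < 0.05


def test_km_censoring_reduces_risk_set_without_step():
    curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
    lookup = dict(zip(curve.times, curve.survival))
    assert lookup[1.0] == pytest.approx(2 / 3)
    assert lookup[2.0] == pytest.approx(2 / 3)  # censoring: no step
    assert lookup[3.0] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def test_logrank_identical_groups_null():
    t = np.array([2.0, 4.0, 6.0, 8.0])
    e = np.ones(4, bool)
    stat, p = logrank_test(t, e, t, e)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_logrank_six_patient_example_matches_permutation_null():
    """Exact permutation null (all 20 group assignments) agrees with the
    chi-square p within 0.02 on a small worked example."""
    times = np.array([1.5, 4.9, 9.7, 5.8, 2.6, 3.3])
    events = np.array([True, True, False, False, True, True])
    ga = np.array([False, True, False, True, True, False])
    obs, p = logrank_test(times[ga], events[ga], times[~ga], events[~ga])
    hits = total = 0
    for comb in itertools.combinations(range(6), 3):
        g = np.zeros(6, bool)
        g[list(comb)] = True
        s, _ = logrank_test(times[g], events[g], times[~g], events[~g])
        total += 1
        hits += s >= obs - 1e-12
    assert abs(p - hits / total) < 0.02


def test_logrank_type_one_error_calibrated():
    """Null rejection rate at alpha=0.05 over 1000 simulated cohorts."""
    rng = np.random.default_rng(123)
    rejections = 0
    for _ in range(1000):
        seed = int(rng.integers(2**31))
        c = generate_cohort(
            CohortSimSpec(n_patients=60, log_hazard_beta=0.0, censor_rate=0.2,
                          seed=seed)
        )
        g = c["group_high"].to_numpy()
        t = c["time_months"].to_numpy()
        e = c["event"].to_numpy(bool)
        _, p = logrank_test(t[g], e[g], t[~g], e[~g])
        rejections += p < 0.05
    assert 0.035 <= rejections / 1000 <= 0.065


def test_logrank_no_events_rejected():
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [False, False], [3.0], [False])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def test_cox_null_beta_recovered_near_zero():
    c = generate_cohort(
        CohortSimSpec(n_patients=2000, log_hazard_beta=0.0, censor_rate=0.0,
                      seed=7)
    )
    res = cox_fit(c.assign(group=c["group_high"].astype(float)), ["group"])
    assert abs(np.log(res.hazard_ratio("group"))) < 0.1
    assert res.converged
    assert res.ties_method == "efron"


def test_cox_recovers_hr3():
    c = generate_cohort(
        CohortSimSpec(n_patients=2000, log_hazard_beta=np.log(3.0),
                      censor_rate=0.0, seed=11)
    )
    res = cox_fit(c.assign(group=c["group_high"].astype(float)), ["group"])
    hr = res.hazard_ratio("group")
    assert 2.6 <= hr <= 3.5
    lo, hi = res.ci("group")
    assert lo <= hr <= hi
    assert res.p_value("group") < 1e-6


def test_cox_ci_coverage():
    """Wald 95% CI covers the true HR in >= 92 of 100 cohorts of n=200."""
    beta = np.log(3.0)
    covered = 0
    for i in range(100):
        c = generate_cohort(
            CohortSimSpec(n_patients=200, log_hazard_beta=beta,
                          censor_rate=0.2, seed=5000 + i)
        )
        res = cox_fit(c.assign(group=c["group_high"].astype(float)), ["group"])
        lo, hi = res.ci("group")
        covered += lo <= np.exp(beta) <= hi
    assert covered >= 92


def test_cox_score_test_close_to_logrank():
    """For one binary covariate the Cox chi-square approximately matches the
    log-rank statistic."""
    c = generate_cohort(
        CohortSimSpec(n_patients=300, log_hazard_beta=np.log(2.0),
                      censor_rate=0.0, seed=9)
    )
    g = c["group_high"].to_numpy()
    t = c["time_months"].to_numpy()
    e = c["event"].to_numpy(bool)
    lr_stat, _ = logrank_test(t[g], e[g], t[~g], e[~g])
    res = cox_fit(c.assign(group=g.astype(float)), ["group"])
    beta = np.log(res.hazard_ratio("group"))
    se = (np.log(res.ci("group")[1]) - beta) / 1.96
    wald_chi2 = (beta / se) ** 2
    assert abs(wald_chi2 - lr_stat) / lr_stat < 0.2


def test_cox_requires_events_and_variation():
    c = generate_cohort(CohortSimSpec(n_patients=50, seed=1))
    with pytest.raises(ValueError):
        cox_fit(c.assign(const=1.0), ["const"])
    c2 = c.copy()
    c2["event"] = False
    with pytest.raises(ValueError):
        cox_fit(c2.assign(group=c2["group_high"].astype(float)), ["group"])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_spearman_monotone_and_inverse():
    x = np.arange(20.0)
    frame = pd.DataFrame({"x": x, "cube": x**3, "neg": -x})
    corr = spearman_matrix(frame)
    assert corr.loc["x", "cube"] == pytest.approx(1.0)
    assert corr.loc["x", "neg"] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T)
    assert corr.loc["x", "x"] == 1.0


def test_spearman_independent_near_zero(rng):
    frame = pd.DataFrame(rng.random((1000, 2)), columns=["a", "b"])
    corr = spearman_matrix(frame)
    assert abs(corr.loc["a", "b"]) < 0.1


def test_spearman_constant_feature_missing():
    frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    corr = spearman_matrix(frame)
    assert np.isnan(corr.loc["a", "c"])
    assert np.isnan(corr.loc["c", "c"])
    assert corr.loc["a", "a"] == 1.0


def test_rank_tests_monotone_invariant(rng):
    a = rng.random(12) * 10
    b = a + rng.normal(0, 1, 12)
    s1 = wilcoxon_signed_rank(a, b)
    s2 = wilcoxon_signed_rank(np.exp(a / 5), np.exp(b / 5))
    # signed ranks depend only on |diff| ordering, which exp changes; but
    # Spearman and Kruskal-Wallis are rank-level invariant:
    g1, g2 = rng.random(8), rng.random(8) + 0.5
    assert kruskal_wallis(g1, g2) == pytest.approx(
        kruskal_wallis(np.exp(g1), np.exp(g2))
    )
    frame = pd.DataFrame({"a": a, "b": b})
    frame2 = pd.DataFrame({"a": a**3, "b": np.exp(b)})
    assert spearman_matrix(frame).loc["a", "b"] == pytest.approx(
        spearman_matrix(frame2).loc["a", "b"]
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def test_wilcoxon_exact_matches_enumeration():
    """Exact p equals full enumeration over all 2^8 sign assignments."""
    d = np.array([1.2, -0.5, 2.3, 0.8, -1.7, 3.1, 0.4, 2.9])
    a = np.zeros(8)
    stat, p = wilcoxon_signed_rank(a + d, a)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=8)
        ]
    )
    p_enum = min(
        1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean())
    )
    assert p == pytest.approx(p_enum)


def test_wilcoxon_identical_pairs_degenerate():
    a = np.arange(8.0)
    with pytest.raises(ValueError):
        wilcoxon_signed_rank(a, a)


def test_wilcoxon_shifted_pairs_power():
    a = np.arange(20.0)
    _, p = wilcoxon_signed_rank(a, a + 1.0)
    assert p < 0.01


def test_wilcoxon_large_n_normal_approximation(rng):
    a = rng.random(40)
    b = a + rng.normal(0.3, 0.5, 40)
    stat, p = wilcoxon_signed_rank(a, b)
    ref = sps.wilcoxon(a, b, correction=True, method="approx")
    assert p == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_kruskal_identical_groups_h_zero():
    g = [1.0, 2.0, 3.0]
    h, p = kruskal_wallis(g, g)
    assert h == pytest.approx(0.0, abs=1e-9)


def test_kruskal_matches_direct_rank_formula():
    groups = [[6.4, 6.8, 7.2], [8.3, 8.7, 9.1, 9.4], [5.1, 5.6]]
    h, p = kruskal_wallis(*groups)
    flat = np.concatenate(groups)
    ranks = sps.rankdata(flat)
    n = len(flat)
    idx = 0
    h_direct = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        idx += len(g)
        h_direct += r.sum() ** 2 / len(g)
    h_direct = 12.0 / (n * (n + 1)) * h_direct - 3 * (n + 1)
    assert h == pytest.approx(h_direct)
    assert p == pytest.approx(sps.chi2.sf(h_direct, len(groups) - 1))


def test_kruskal_permutation_p_close_to_chi_square(rng):
    groups = [
        np.array([0.35, 0.82, 0.33, -1.3, 0.91, 0.45, -0.54, 0.58]),
        np.array([0.86, 0.79, 0.53, 1.05, -0.24, 0.34, 0.02, 1.1]),
        np.array([0.94, 0.61, 0.12, 0.64, 0.91, 0.62, 2.19, 1.91]),
    ]
    h_obs, p = kruskal_wallis(*groups)
    flat = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    hits = 0
    reps = 5000
    for _ in range(reps):
        perm = rng.permutation(flat)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        h, _ = kruskal_wallis(*parts)
        hits += h >= h_obs - 1e-12
    assert abs(p - hits / reps) < 0.02


def test_kruskal_degenerate_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([2.0, 2.0, 2.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# cutoffs and stratification
# ---------------------------------------------------------------------------


def test_dichotomize_mean_rule():
    res = dichotomize(np.array([1.0, 2.0, 3.0, 4.0]), CutoffRule("mean"))
    assert res.cutoff == 2.5
    assert list(res.high) == [False, False, True, True]


def test_dichotomize_fixed_rule_ignores_data():
    res = dichotomize(np.array([1.0, 100.0]), CutoffRule("fixed", 43.1))
    assert res.cutoff == 43.1
    assert list(res.high) == [False, True]


def test_dichotomize_median_rule():
    res = dichotomize(np.array([1.0, 2.0, 3.0, 10.0]), CutoffRule("median"))
    assert res.cutoff == 2.5


def test_dichotomize_youden_perfect_separation():
    values = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
    events = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
    res = dichotomize(values, CutoffRule("roc_youden"), events)
    high = res.high
    # perfect separation: J = 1 at the chosen cutoff
    tpr = (high & events).sum() / events.sum()
    fpr = (high & ~events).sum() / (~events).sum()
    assert tpr - fpr == pytest.approx(1.0)


def test_dichotomize_youden_single_class_rejected():
    with pytest.raises(ValueError):
        dichotomize(
            np.array([1.0, 2.0]), CutoffRule("roc_youden"),
            np.array([True, True]),
        )


def test_cutoff_rule_validation():
    with pytest.raises(ValueError):
        CutoffRule("fixed")
    with pytest.raises(ValueError):
        CutoffRule("mean", 5.0)
    with pytest.raises(ValueError):
        CutoffRule("quartile")


def test_two_marker_strata_labels():
    cohort = pd.DataFrame(
        {
            "a": [10.0, 10.0, 1.0, 1.0],
            "b": [10.0, 1.0, 10.0, 1.0],
            "event": [True, True, False, False],
        }
    )
    labels, cutoffs = two_marker_strata(
        cohort, "a", CutoffRule("mean"), "b", CutoffRule("median")
    )
    assert list(labels) == ["both_high", "other", "other", "other"]
    assert cutoffs["a"] == pytest.approx(5.5)


def test_two_marker_strata_interaction_power():
    """Excess hazard confined to the double-high stratum is detected by
    log-rank at n=200."""
    rng = np.random.default_rng(17)
    n = 200
    a, b = rng.lognormal(3, 1, n), rng.lognormal(3, 1, n)
    both = (a >= a.mean()) & (b >= np.median(b))
    hazard = 0.02 * np.where(both, 3.0, 1.0)
    t = rng.exponential(1 / hazard)
    e = np.ones(n, bool)
    cohort = pd.DataFrame({"a": a, "b": b, "event": e})
    labels, _ = two_marker_strata(
        cohort, "a", CutoffRule("mean"), "b", CutoffRule("median")
    )
    hi = labels == "both_high"
    _, p = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
    assert p < 0.05
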