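"""Summaries, rank tests vs enumeration oracles, ANOVA, categorization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tadfish import (aggregate_experiments, allele_pair_correlation,
                     categorize_p, compare_experiment_means, kruskal_dunn,
                     ks_test, mann_whitney, summarize_distances)
from tadfish.stats import bonferroni


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summary_interpolated_quartiles():
    s = summarize_distances([0.1, 0.2, 0.3, 0.4], threshold_um=0.25)
    assert s.median_um == pytest.approx(0.25)
    assert s.iqr_um == pytest.approx(0.325 - 0.175)
    assert s.interaction_fraction == pytest.approx(0.5)


def test_summary_degenerate_inputs():
    s = summarize_distances([0.7])
    assert (s.median_um, s.iqr_um) == (0.7, 0.0)
    assert summarize_distances([0.3] * 5).iqr_um == 0.0
    with pytest.raises(ValueError):
        summarize_distances([])


def test_aggregate_experiments_mean_of_medians():
    agg = aggregate_experiments([0.30, 0.34, 0.32])
    assert agg.mean_of_medians_um == pytest.approx(0.32)
    assert agg.sd_um == pytest.approx(np.std([0.30, 0.34, 0.32], ddof=1))
    assert agg.sem_um == pytest.approx(agg.sd_um / np.sqrt(3))
    assert agg.n_experiments == 3


# ---------------------------------------------------------------------------
# Mann-Whitney against the exhaustive permutation oracle
# ---------------------------------------------------------------------------

def _permutation_p(a, b):
    """Two-sided p over all C(n_a + n_b, n_a) group labelings (no ties)."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        return sum((x > y) for x in aa for y in bb)

    u_obs = u_stat(range(na))
    mid = na * len(b) / 2
    total, extreme = 0, 0
    for comb in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(comb) - mid) >= abs(u_obs - mid):
            extreme += 1
    return extreme / total


def test_separated_samples_exact_p():
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(0.1)  # 2 / C(6,3)
    assert r.extra["method"] == "exact"


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_small_sample_p_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=3)
    b = rng.normal(0.5, size=3)
    r = mann_whitney(a, b)
    assert r.p_value == pytest.approx(_permutation_p(a, b), abs=1e-12)


def test_identical_samples_p_near_one():
    x = [0.1, 0.4, 0.7, 0.9, 1.3]
    r = mann_whitney(x, x)
    assert r.p_value >= 0.95
    # symmetric in group order
    assert mann_whitney(x, [2, 3, 4]).p_value == pytest.approx(
        mann_whitney([2, 3, 4], x).p_value)
    with pytest.raises(ValueError):
        mann_whitney([], x)


def test_mann_whitney_null_calibration():
    """Type-I error at alpha=0.05 under the null, 2000 replicates."""
    rejections = 0
    n_rep = 2000
    rng = np.random.default_rng(123)
    for _ in range(n_rep):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        rejections += mann_whitney(a, b).p_value < 0.05
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rejections / n_rep - 0.05) <= 3 * se


# ---------------------------------------------------------------------------
# KS
# ---------------------------------------------------------------------------

def test_ks_trivial_and_brute_force_d():
    assert ks_test([1, 2, 3], [1, 2, 3]).statistic == 0.0
    assert ks_test([1, 2], [5, 6]).statistic == 1.0
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=12), rng.normal(0.4, size=9)
    d = ks_test(a, b).statistic
    # explicit ECDF scan over all breakpoints
    grid = np.concatenate([a, b])
    ecdf_a = np.array([(a <= x).mean() for x in grid])
    ecdf_b = np.array([(b <= x).mean() for x in grid])
    assert d == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def test_identical_groups_are_null():
    x = [1.0, 2.0, 3.0, 4.0]
    results = kruskal_dunn([x, x, x])
    kw = results[0]
    assert kw.statistic == pytest.approx(0.0, abs=1e-9)
    assert all(r.p_value == 1.0 for r in results[1:])
    assert len(results) == 1 + 3


def test_dunn_agrees_with_rank_sum_on_separated_groups():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 60)
    b = rng.normal(2, 1, 60)
    dunn = kruskal_dunn([a, b])[1]
    mw = mann_whitney(a, b)
    assert (dunn.p_value < 0.05) == (mw.p_value < 0.05) == True  # noqa: E712


def test_bonferroni_arithmetic_and_monotonicity():
    np.testing.assert_allclose(bonferroni([0.02], 3), [0.06])
    p = np.array([0.001, 0.2, 0.9])
    assert np.all(bonferroni(p, 4) >= p)
    assert bonferroni([0.6], 3)[0] == 1.0  # capped


# ---------------------------------------------------------------------------
# two-way ANOVA on per-experiment medians
# ---------------------------------------------------------------------------

def _medians_frame(values):
    rows = []
    for (cond, locus), vals in values.items():
        rows += [{"condition": cond, "locus": locus, "median_um": v}
                 for v in vals]
    return pd.DataFrame(rows)


def test_equal_medians_give_null_condition_effect():
    df = _medians_frame({("ctrl", "a"): [0.3, 0.3], ("drug", "a"): [0.3, 0.3],
                         ("ctrl", "b"): [0.3, 0.3], ("drug", "b"): [0.3, 0.3]})
    res = {r.test_name: r for r in compare_experiment_means(df)}
    assert res["anova[condition]"].p_value == 1.0
    assert res["anova[condition]"].statistic == pytest.approx(0.0)


def test_additive_effects_with_zero_noise_are_maximal():
    df = _medians_frame({("ctrl", "a"): [0.3, 0.3], ("drug", "a"): [0.5, 0.5],
                         ("ctrl", "b"): [0.4, 0.4], ("drug", "b"): [0.6, 0.6]})
    res = {r.test_name: r for r in compare_experiment_means(df)}
    assert res["anova[condition]"].p_value == pytest.approx(0.0)
    assert np.isinf(res["anova[condition]"].statistic)


def test_single_experiment_cell_is_rejected():
    df = _medians_frame({("ctrl", "a"): [0.3], ("drug", "a"): [0.4, 0.5]})
    with pytest.raises(ValueError, match="fewer than 2 experiments"):
        compare_experiment_means(df)


def test_contrast_bonferroni_uses_locus_count():
    rng = np.random.default_rng(8)
    df = _medians_frame({
        ("ctrl", "a"): rng.normal(0.3, 0.02, 4), ("drug", "a"): rng.normal(0.31, 0.02, 4),
        ("ctrl", "b"): rng.normal(0.4, 0.02, 4), ("drug", "b"): rng.normal(0.4, 0.02, 4)})
    res = {r.test_name: r for r in compare_experiment_means(df)}
    for loc in ("a", "b"):
        c = res[f"contrast[{loc}:ctrl-drug]"]
        assert c.extra["n_comparisons"] == 2
        assert c.p_value == pytest.approx(
            min(1.0, c.extra["p_raw"] * 2))


# ---------------------------------------------------------------------------
# allele-pair correlation
# ---------------------------------------------------------------------------

def _pairs_frame(pairs):
    rows = []
    for i, (d1, d2) in enumerate(pairs, start=1):
        rows.append({"cell_id": i, "distance_2d_um": d1})
        rows.append({"cell_id": i, "distance_2d_um": d2})
    return pd.DataFrame(rows)


def test_duplicated_pairs_give_r_one():
    d = np.linspace(0.1, 1.0, 20)
    res = allele_pair_correlation(_pairs_frame(list(zip(d, d))), seed=0)
    assert res["pearson"].statistic == pytest.approx(1.0)


def test_anti_ordered_pairs_give_r_minus_one():
    d = np.linspace(0.1, 1.0, 20)
    res = allele_pair_correlation(_pairs_frame(list(zip(d, -d))), seed=0)
    assert res["pearson"].statistic == pytest.approx(-1.0)


def test_independent_pairs_are_uncorrelated():
    rng = np.random.default_rng(17)
    ok = 0
    n, n_seeds = 2000, 20
    for seed in range(n_seeds):
        pairs = rng.random((n, 2))
        res = allele_pair_correlation(_pairs_frame(pairs), seed=seed)
        ok += abs(res["pearson"].statistic) < 3 / np.sqrt(n)
    assert ok >= n_seeds - 1


def test_too_few_pairs_raises():
    with pytest.raises(ValueError, match="at least 3"):
        allele_pair_correlation(_pairs_frame([(0.1, 0.2), (0.3, 0.4)]), seed=0)


# ---------------------------------------------------------------------------
# significance categories
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,scheme,label", [
    (0.04, "methods", "*"),
    (0.05, "methods", "ns"),
    (0.009, "methods", "**"),
    (0.0009, "methods", "***"),
    (1e-25, "fig2", "**"),
    (1e-101, "fig2", "***"),
    (1e-5, "fig2", "*"),
    (0.02, "fig2", "ns"),
])
def test_categorize_p(p, scheme, label):
    assert categorize_p(p, scheme) == label


def test_categorize_p_rejects_invalid():
    with pytest.raises(ValueError):
        categorize_p(1.5)
    with pytest.raises(ValueError):
        categorize_p(0.5, scheme="bogus")
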