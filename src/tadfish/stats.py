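"""Nonparametric comparison layer for boundary-distance distributions.

Implements the statistical toolkit of the allele-distance analysis:
median/IQR summaries, two-sample Mann-Whitney (Wilcoxon rank-sum) and
Kolmogorov-Smirnov tests, Kruskal-Wallis with Dunn-Bonferroni post hocs,
per-experiment mean-of-medians aggregation with a two-way ANOVA on the
experiment medians, within-nucleus allele-pair correlation, and the
significance-category schemes used for reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Mann-Whitney switches from exact enumeration to the tie-corrected normal
#: approximation above this product of group sizes
EXACT_MW_MAX_PRODUCT = 400

P_SCHEMES = ("methods", "fig2")


@dataclass
class DistanceSummary:
    n: int
    median_um: float
    iqr_um: float
    interaction_fraction: float
    threshold_um: float


@dataclass
class ExperimentAggregate:
    """Mean of per-experiment medians with SD and SEM dispersion."""

    medians_um: tuple[float, ...]
    mean_of_medians_um: float
    sd_um: float
    sem_um: float
    n_experiments: int


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    category: str
    group_ns: tuple[int, ...]
    extra: dict = field(default_factory=dict)


def categorize_p(p: float, scheme: str = "methods") -> str:
    """Map a p-value to a significance category label.

    ``methods`` scheme: *** p<0.001, ** p<0.01, * p<0.05, ns p>=0.05.
    ``fig2`` scheme (for the huge-n distribution comparisons):
    *** p<1e-100, ** 1e-100<=p<1e-20, * 1e-20<=p<0.01, ns otherwise.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if scheme == "methods":
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"
    if scheme == "fig2":
        if p < 1e-100:
            return "***"
        if p < 1e-20:
            return "**"
        if p < 0.01:
            return "*"
        return "ns"
    raise ValueError(f"unknown scheme {scheme!r}; choose from {P_SCHEMES}")


def _result(name, stat, p, ns, scheme="methods", **extra) -> TestResult:
    return TestResult(test_name=name, statistic=float(stat),
                      p_value=float(p), category=categorize_p(p, scheme),
                      group_ns=tuple(int(n) for n in ns), extra=extra)


def summarize_distances(distances_um, threshold_um: float = 0.250) -> DistanceSummary:
    """Median, IQR (Q3-Q1, linear-interpolation quantiles) and the
    interaction fraction at ``threshold_um``."""
    d = np.asarray(distances_um, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("summarize_distances needs at least one value")
    q1, med, q3 = np.percentile(d, [25, 50, 75])  # linear interpolation
    frac = float((d < threshold_um).sum() / d.size)
    return DistanceSummary(n=int(d.size), median_um=float(med),
                           iqr_um=float(q3 - q1), interaction_fraction=frac,
                           threshold_um=threshold_um)


def aggregate_experiments(per_experiment_medians) -> ExperimentAggregate:
    """Mean of per-experiment medians, with SD and SEM of the medians."""
    m = np.asarray(per_experiment_medians, dtype=float)
    if m.size == 0:
        raise ValueError("need at least one experiment median")
    sd = float(np.std(m, ddof=1)) if m.size > 1 else 0.0
    return ExperimentAggregate(
        medians_um=tuple(float(x) for x in m),
        mean_of_medians_um=float(m.mean()),
        sd_um=sd, sem_um=sd / np.sqrt(m.size), n_experiments=int(m.size))


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def _check_groups(*groups):
    arrays = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
        arrays.append(a)
    return arrays


def mann_whitney(a, b, scheme: str = "methods") -> TestResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null enumeration when ``n_a * n_b <= EXACT_MW_MAX_PRODUCT`` and the
    pooled sample has no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a, b = _check_groups(a, b)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = (a.size * b.size <= EXACT_MW_MAX_PRODUCT) and no_ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return _result("mann_whitney", res.statistic, res.pvalue,
                   (a.size, b.size), scheme, method="exact" if exact else "asymptotic")


def ks_test(a, b, scheme: str = "methods") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a, b = _check_groups(a, b)
    res = sps.ks_2samp(a, b, method="asymp")
    return _result("ks", res.statistic, res.pvalue, (a.size, b.size), scheme)


# ---------------------------------------------------------------------------
# multi-group: Kruskal-Wallis + Dunn with Bonferroni correction
# ---------------------------------------------------------------------------

def kruskal_dunn(groups: Sequence, labels: Optional[Sequence[str]] = None,
                 scheme: str = "methods") -> list[TestResult]:
    """Kruskal-Wallis H followed by pairwise Dunn z tests.

    Dunn's statistic compares mean ranks of the pooled sample with the
    tie-corrected rank variance; each pairwise p is multiplied by the number
    of comparisons (Bonferroni) and capped at 1.  Returns the Kruskal-Wallis
    result first, then one result per pair with raw and adjusted p in
    ``extra``.
    """
    arrays = _check_groups(*groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(arrays))]

    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        h, p_kw = 0.0, 1.0  # identical groups: H is 0 by construction
    else:
        h, p_kw = sps.kruskal(*arrays)
    results = [_result("kruskal_wallis", h, p_kw,
                       [a.size for a in arrays], scheme)]

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum over tie groups of (t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean()
                  for i in range(len(arrays))]
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_comp = len(arrays) * (len(arrays) - 1) // 2
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_comp)
        r = _result(f"dunn[{labels[i]}-{labels[j]}]", z, p_adj,
                    (sizes[i], sizes[j]), scheme,
                    p_raw=float(p_raw), n_comparisons=n_comp)
        results.append(r)
    return results


def bonferroni(p_values, n_comparisons: Optional[int] = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    k = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(1.0, p * k)


# ---------------------------------------------------------------------------
# per-experiment aggregation: two-way ANOVA on experiment medians
# ---------------------------------------------------------------------------

def compare_experiment_means(medians: pd.DataFrame, scheme: str = "methods"
                             ) -> list[TestResult]:
    """Two-way fixed-effects ANOVA on per-experiment medians.

    ``medians`` needs columns ``median_um``, ``condition`` and ``locus``; the
    replicate unit is the independent experiment.  Every condition x locus
    cell must hold at least two experiments (otherwise the distribution-level
    rank tests are the right tool and an error says so).  Returns the two
    main effects and the interaction, followed by the condition contrast
    within each locus: a t test on the pooled residual mean square, with the
    p-value Bonferroni-multiplied by the number of contrasts.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"median_um", "condition", "locus"}
    if not required.issubset(medians.columns):
        raise ValueError(f"medians must have columns {sorted(required)}")
    counts = medians.groupby(["condition", "locus"]).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"cells {bad} have fewer than 2 experiments; use the "
            "distribution-level test (mann_whitney) instead")

    model = smf.ols("median_um ~ C(condition) * C(locus)", data=medians).fit()
    if model.df_resid <= 0 or not np.isfinite(model.mse_resid):
        raise ValueError("ANOVA design has no residual degrees of freedom")
    anova = sm.stats.anova_lm(model, typ=2)
    total_n = len(medians)
    # round-off guard: sums of squares below this are structurally zero
    scale = max(np.max(np.abs(medians["median_um"])), 1.0)
    ss_tol = total_n * (1e3 * np.finfo(float).eps * scale) ** 2
    resid_zero = anova.loc["Residual", "sum_sq"] <= ss_tol
    results = []
    name_map = {"C(condition)": "anova[condition]",
                "C(locus)": "anova[locus]",
                "C(condition):C(locus)": "anova[interaction]"}
    for key, name in name_map.items():
        if key not in anova.index:
            continue
        f = anova.loc[key, "F"]
        p = anova.loc[key, "PR(>F)"]
        if anova.loc[key, "sum_sq"] <= ss_tol:  # no effect at all
            f, p = 0.0, 1.0
        elif resid_zero or not np.isfinite(f):  # zero residual variance
            f, p = np.inf, 0.0
        results.append(_result(name, f, p, (total_n,), scheme,
                               df=float(anova.loc[key, "df"])))

    # Bonferroni post hoc: condition contrast within each locus, pooled MSE
    mse = 0.0 if resid_zero else model.mse_resid
    df_resid = model.df_resid
    loci = sorted(medians["locus"].unique())
    conditions = sorted(medians["condition"].unique())
    contrasts = [(loc, ca, cb) for loc in loci
                 for ca, cb in itertools.combinations(conditions, 2)]
    n_comp = len(contrasts)
    for loc, ca, cb in contrasts:
        ga = medians.query("locus == @loc and condition == @ca")["median_um"]
        gb = medians.query("locus == @loc and condition == @cb")["median_um"]
        diff = ga.mean() - gb.mean()
        if abs(diff) <= 1e3 * np.finfo(float).eps * scale:
            diff = 0.0
        se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
        if se == 0:
            t, p_raw = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
        else:
            t = diff / se
            p_raw = 2.0 * sps.t.sf(abs(t), df_resid)
        p_adj = min(1.0, p_raw * n_comp)
        results.append(_result(f"contrast[{loc}:{ca}-{cb}]", t, p_adj,
                               (len(ga), len(gb)), scheme,
                               p_raw=float(p_raw), n_comparisons=n_comp,
                               mean_difference_um=float(diff)))
    return results


# ---------------------------------------------------------------------------
# within-nucleus allele correlation
# ---------------------------------------------------------------------------

def allele_pair_correlation(alleles: pd.DataFrame, seed: int = 0,
                            distance_col: str = "distance_2d_um",
                            scheme: str = "methods") -> dict[str, TestResult]:
    """Correlation of the two boundary distances within each nucleus.

    Uses nuclei carrying exactly two alleles.  Because allele identity within
    a nucleus is arbitrary, the (first, second) order of each pair is
    randomized with a seeded generator before computing Pearson r and
    Spearman rho.
    """
    two = alleles.groupby("cell_id").filter(lambda g: len(g) == 2)
    pairs = (two.sort_values(["cell_id"])
             .groupby("cell_id")[distance_col].apply(list))
    pairs = pairs[pairs.apply(lambda p: all(np.isfinite(p)))]
    if len(pairs) < 3:
        raise ValueError("need at least 3 two-allele nuclei")
    arr = np.array(pairs.tolist(), dtype=float)
    rng = np.random.default_rng(seed)
    flip = rng.random(len(arr)) < 0.5
    arr[flip] = arr[flip, ::-1]
    r, p_r = sps.pearsonr(arr[:, 0], arr[:, 1])
    rho, p_s = sps.spearmanr(arr[:, 0], arr[:, 1])
    n = (len(arr), len(arr))
    return {"pearson": _result("pearson_r", r, p_r, n, scheme),
            "spearman": _result("spearman_rho", rho, p_s, n, scheme)}
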