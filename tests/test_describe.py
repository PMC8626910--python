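"""Downstream statistics: rank tests, correlations, PCA, clustering,
demographics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csfpanel as cp
from csfpanel.describe import freeman_halton_2xk


# ---------------------------------------------------------------- wilcoxon

def test_wilcoxon_identical_samples():
    x = np.array([1.0, 2.0, 3.0])
    assert cp.wilcoxon_rank_sum(x, x.copy())[1] == 1.0


def test_wilcoxon_exact_matches_enumeration():
    x = np.array([1.2, 3.4, 5.1, 7.7])
    y = np.array([2.0, 2.9, 6.0, 9.3])
    _, p = cp.wilcoxon_rank_sum(x, y)
    # enumerate all C(8,4) assignments of ranks to the first sample
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:4].sum()
    mean_w = 4 * 9 / 2
    count = 0
    combos = list(itertools.combinations(range(8), 4))
    for c in combos:
        w = ranks[list(c)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    assert abs(p - count / len(combos)) < 1e-12


def test_wilcoxon_exact_close_to_normal_approximation():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 15)
    y = rng.normal(0.8, 1, 15)
    p_auto = cp.wilcoxon_rank_sum(x, y)[1]  # asymptotic (n=30)
    p_exact = stats.mannwhitneyu(x, y, method="exact").pvalue
    assert abs(p_auto - p_exact) < 0.01


def test_wilcoxon_power_on_planted_marker():
    # the strongest planted protein separates groups at cohort sample sizes
    hits = 0
    n_sims = 20
    for seed in range(n_sims):
        cohort = cp.generate_cohort(cp.CohortSpec(seed=seed))
        m, s, _ = cp.generate_assay(cohort, cp.EffectSpec(), cp.AssaySpec(),
                                    seed=seed)
        sel = cp.select_comparison_cohort(s, cp.ComparisonConfig())
        v = m.loc[sel["sample_id"], "NEFM"].to_numpy()
        lab = sel["label"].to_numpy()
        _, p = cp.wilcoxon_rank_sum(v[lab == 1], v[lab == 0])
        hits += p < 0.05
    assert hits >= 0.95 * n_sims


# ---------------------------------------------------------------- spearman

def test_spearman_monotone_transform_gives_unity():
    x = np.random.default_rng(1).normal(size=50)
    m = pd.DataFrame({"a": x, "b": np.exp(x)})
    r = cp.spearman_matrix(m)
    assert abs(r.loc["a", "b"] - 1.0) < 1e-12
    assert (r.to_numpy().diagonal() == 1.0).all()


def test_spearman_five_point_rank_formula_with_midranks():
    a = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
    b = np.array([3.0, 1.0, 4.0, 4.0, 5.0])
    r = cp.spearman_matrix(pd.DataFrame({"a": a, "b": b})).loc["a", "b"]
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    expected = np.corrcoef(ra, rb)[0, 1]  # Pearson of midranks
    assert abs(r - expected) < 1e-12


def test_spearman_constant_column_nan_with_warning():
    m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5],
                      "c": [2.0, 1, 4, 3]})
    with pytest.warns(UserWarning, match="constant"):
        r = cp.spearman_matrix(m)
    assert np.isnan(r.loc["a", "b"]) and np.isnan(r.loc["b", "c"])
    assert r.loc["b", "b"] == 1.0
    assert np.isfinite(r.loc["a", "c"])


# --------------------------------------------------------------------- pca

def test_pca_two_perfectly_correlated_proteins():
    x = np.abs(np.random.default_rng(2).normal(size=40)) + 0.5
    m = pd.DataFrame({"a": x, "b": x ** 2})  # identical after log+scale? no,
    # but log(b) = 2 log(a): perfectly correlated
    res = cp.pca_log(m)
    assert abs(res.explained_pct[0] - 100.0) < 1e-9


def test_pca_matches_direct_svd():
    rng = np.random.default_rng(3)
    m = pd.DataFrame(rng.lognormal(1.0, 0.4, size=(6, 4)))
    res = cp.pca_log(m)
    L = np.log(m.to_numpy())
    L = L - L.mean(0)
    L = L / L.std(0)
    sv = np.linalg.svd(L, compute_uv=False)
    np.testing.assert_allclose(res.explained_pct,
                               100 * sv ** 2 / (sv ** 2).sum(), rtol=1e-10)
    assert abs(res.explained_pct.sum() - 100.0) < 1e-9
    # contributions sum to 100 per PC
    np.testing.assert_allclose(res.contributions_pct.sum(axis=0), 100.0,
                               rtol=1e-9)
    # scores orthogonal across PCs
    G = res.scores.to_numpy().T @ res.scores.to_numpy()
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8


def test_pca_rejects_nonpositive():
    m = pd.DataFrame({"a": [1.0, -2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="strictly positive"):
        cp.pca_log(m)


# -------------------------------------------------------------- clustering

def brute_average_linkage(points):
    """Naive UPGMA: merge the two clusters with the smallest mean pairwise
    Euclidean distance until one remains; returns the merge heights."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([np.linalg.norm(points[a] - points[b])
                             for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def _pca_of_points(pts):
    """Wrap raw 2-D points as a PcaResult so hcluster_pc can consume them."""
    from csfpanel.describe import PcaResult
    scores = pd.DataFrame(pts, columns=["PC1", "PC2"])
    return PcaResult(scores=scores, explained_pct=np.array([60.0, 40.0]),
                     contributions_pct=pd.DataFrame())


def test_three_separated_clouds_recovered():
    rng = np.random.default_rng(4)
    pts = np.vstack([rng.normal(c, 0.1, size=(10, 2))
                     for c in ([0, 0], [10, 0], [0, 10])])
    res = cp.hcluster_pc(_pca_of_points(pts), n_pcs=2, k=3)
    truth = np.repeat([0, 1, 2], 10)
    # each recovered cluster is exactly one cloud
    for cid in (1, 2, 3):
        members = truth[res.assignments.to_numpy() == cid]
        assert len(set(members)) == 1
    assert res.k == 3


def test_merge_heights_match_bruteforce_on_six_points():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(6, 2))
    res = cp.hcluster_pc(_pca_of_points(pts), n_pcs=2, k=1)
    np.testing.assert_allclose(sorted(res.linkage_matrix[:, 2]),
                               sorted(brute_average_linkage(pts)), rtol=1e-10)


def test_k_equals_n_gives_singletons_and_k_too_large_rejected():
    pts = np.random.default_rng(6).normal(size=(5, 2))
    res = cp.hcluster_pc(_pca_of_points(pts), n_pcs=2, k=5)
    assert sorted(res.assignments) == [1, 2, 3, 4, 5]
    with pytest.raises(ValueError, match="k exceeds"):
        cp.hcluster_pc(_pca_of_points(pts), n_pcs=2, k=6)


def test_clusters_numbered_by_increasing_size():
    pts = np.vstack([np.random.default_rng(7).normal(c, 0.05, size=(n, 2))
                     for c, n in zip(([0, 0], [5, 5], [9, 0]), (2, 7, 21))])
    res = cp.hcluster_pc(_pca_of_points(pts), n_pcs=2, k=3)
    sizes = res.assignments.value_counts().sort_index()
    assert list(sizes) == [2, 7, 21]


def test_cluster_composition_purities():
    from csfpanel.describe import ClusterResult
    assign = pd.Series([1] * 27 + [2] * 184,
                       index=[f"s{i}" for i in range(211)], name="cluster")
    labels = (["affected"] * 25 + ["unaffected"] * 2
              + ["affected"] * 13 + ["unaffected"] * 171)
    comp = cp.cluster_composition(
        ClusterResult(assignments=assign, k=2, linkage_matrix=np.empty((0, 4))),
        labels)
    row1 = comp[comp.cluster == 1].iloc[0]
    row2 = comp[comp.cluster == 2].iloc[0]
    assert row1.purity_pct == 93 and row1.majority_label == "affected"
    assert row2.purity_pct == 93 and row2.majority_label == "unaffected"
    # size-weighted purity equals overall majority-class agreement
    agree = (comp.purity_fraction * comp["size"]).sum() / comp["size"].sum()
    maj = pd.Series(labels).groupby(assign.to_numpy()).agg(
        lambda s: s.value_counts().max()).sum() / len(labels)
    assert abs(agree - maj) < 1e-12


def test_single_label_cluster_is_pure():
    from csfpanel.describe import ClusterResult
    assign = pd.Series([1] * 4, index=list("abcd"), name="cluster")
    comp = cp.cluster_composition(
        ClusterResult(assignments=assign, k=1, linkage_matrix=np.empty((0, 4))),
        ["x"] * 4)
    assert comp.iloc[0].purity_pct == 100


# ------------------------------------------------------------ demographics

def test_freeman_halton_2x2_matches_fisher_exact():
    table = [[8, 2], [1, 5]]
    p_fh = freeman_halton_2xk(table)
    p_sp = stats.fisher_exact(np.array(table)).pvalue
    assert abs(p_fh - p_sp) < 1e-12


def test_group_balance_on_cohort_like_table():
    # sex split 20/27, 58/40, 41/35 across three groups
    rows = []
    for g, (f, m) in (("AMC", (20, 27)), ("PMC", (58, 40)), ("NC", (41, 35))):
        rng = np.random.default_rng(hash(g) % 2 ** 31)
        for i in range(f + m):
            rows.append({"group": g, "sex": "F" if i < f else "M",
                         "age": rng.uniform(30, 70)})
    rep = cp.group_balance_tests(pd.DataFrame(rows))
    assert round(rep["sex_fisher_p"], 2) == 0.17
    assert set(rep["age_tukey_p"]) == {"AMC_vs_PMC", "AMC_vs_NC", "PMC_vs_NC"}


def test_identical_age_groups_give_zero_f():
    ages = list(np.linspace(40, 60, 10))
    df = pd.DataFrame({
        "group": ["A"] * 10 + ["B"] * 10,
        "sex": ["F", "M"] * 10,
        "age": ages + ages,
    })
    rep = cp.group_balance_tests(df)
    assert rep["age_anova_F"] < 1e-12
    assert rep["age_anova_p"] > 0.99


def test_small_group_excluded_from_anova_with_warning():
    df = pd.DataFrame({
        "group": ["A"] * 10 + ["B"] * 10 + ["C"],
        "sex": (["F", "M"] * 10) + ["F"],
        "age": list(np.random.default_rng(8).uniform(30, 70, 20)) + [50.0],
    })
    with pytest.warns(UserWarning, match="excluded from ANOVA"):
        rep = cp.group_balance_tests(df)
    assert set(rep["age_tukey_p"]) == {"A_vs_B"}
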