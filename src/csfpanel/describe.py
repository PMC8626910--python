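"""Univariate and unsupervised characterization of selected panels.

Wilcoxon rank-sum comparisons, Spearman correlation matrices, PCA on
log-transformed intensities, hierarchical clustering of principal
component scores (Euclidean distance, average linkage), cluster
composition summaries, and cohort demographic balance tests (exact
Freeman-Halton test on sex x group; one-way ANOVA with Tukey HSD on
age).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import lgamma
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.preprocessing import StandardScaler

__all__ = [
    "wilcoxon_rank_sum", "spearman_matrix", "PcaResult", "pca_log",
    "ClusterResult", "hcluster_pc", "cluster_composition",
    "freeman_halton_2xk", "group_balance_tests",
]


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when m + n <= 20 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    Returns ``(U statistic of x, p)``; identical pooled values give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(matrix, proteins: Optional[Sequence[str]] = None,
                    ) -> pd.DataFrame:
    """Pairwise Spearman correlations (midranks for ties)."""
    m = matrix[list(proteins)] if proteins is not None else matrix
    if len(m) < 3:
        raise ValueError("need at least 3 samples")
    V = m.to_numpy(float)
    const = np.ptp(V, axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant protein column(s) {list(m.columns[const])}: "
            "correlation undefined, recorded as NaN")
    # Spearman = Pearson correlation of midranks (robust to constant
    # columns, which scipy.spearmanr collapses to a scalar NaN)
    ranks = np.apply_along_axis(stats.rankdata, 0, V)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = np.corrcoef(ranks.T)
    rho = np.asarray(rho, float)
    if rho.ndim == 0:  # single-protein panel
        rho = rho.reshape(1, 1)
    rho[np.ix_(const, ~const)] = np.nan
    rho[np.ix_(~const, const)] = np.nan
    rho[np.ix_(const, const)] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=m.columns, columns=m.columns)


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x PCs
    explained_pct: np.ndarray       # % of total variance per PC (sums to 100)
    contributions_pct: pd.DataFrame  # variables x PCs, each column sums to 100


def pca_log(matrix, proteins: Optional[Sequence[str]] = None,
            standardize: bool = True) -> PcaResult:
    """PCA of natural-log intensities (correlation-matrix PCA by default).

    Variables are centred and, with ``standardize``, scaled to unit
    variance before the eigendecomposition; per-variable contributions
    are squared loadings in percent.
    """
    m = matrix[list(proteins)] if proteins is not None else matrix
    if len(m) < 2:
        raise ValueError("need at least 2 samples")
    V = m.to_numpy(float)
    if np.any(V <= 0):
        raise ValueError("intensities must be strictly positive for log PCA")
    L = np.log(V)
    L = L - L.mean(axis=0)
    if standardize:
        sd = L.std(axis=0)
        L = L / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    k = len(s)
    scores = U * s
    ev = s ** 2
    explained = 100.0 * ev / ev.sum()
    contrib = 100.0 * (Vt ** 2)  # rows of Vt are unit-norm loadings
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.index, columns=pcs),
        explained_pct=explained,
        contributions_pct=pd.DataFrame(contrib.T, index=m.columns, columns=pcs))


@dataclass
class ClusterResult:
    assignments: pd.Series   # sample -> cluster id (1..k, numbered by size)
    k: int
    linkage_matrix: np.ndarray


def hcluster_pc(pca: PcaResult, n_pcs: int = 2, k: int = 3) -> ClusterResult:
    """Average-linkage (UPGMA) Euclidean clustering of the first PCs.

    The dendrogram is cut into ``k`` clusters, renumbered 1..k by
    increasing size (ties by first occurrence).
    """
    if n_pcs > pca.scores.shape[1]:
        raise ValueError("n_pcs exceeds available components")
    pts = pca.scores.iloc[:, :n_pcs].to_numpy()
    if k > len(pts):
        raise ValueError("k exceeds the number of samples")
    Z = linkage(pts, method="average", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sizes.sort_values(kind="stable").index  # increasing size
    remap = {old: new + 1 for new, old in enumerate(order)}
    assign = pd.Series([remap[c] for c in raw], index=pca.scores.index,
                       name="cluster")
    return ClusterResult(assignments=assign, k=int(assign.max()),
                         linkage_matrix=Z)


def cluster_composition(clusters: ClusterResult, labels) -> pd.DataFrame:
    """Per-cluster label counts, majority label and purity.

    Purity is the majority-class share, reported both as a fraction and
    rounded half-up to integer percent.
    """
    labels = pd.Series(np.asarray(labels), index=clusters.assignments.index)
    rows = []
    for cid in sorted(clusters.assignments.unique()):
        mask = clusters.assignments == cid
        counts = labels[mask].value_counts()
        majority = counts.idxmax()
        frac = counts.max() / mask.sum()
        rows.append({
            "cluster": int(cid),
            "size": int(mask.sum()),
            "majority_label": majority,
            "purity_fraction": float(frac),
            "purity_pct": int(np.floor(100 * frac + 0.5)),
            **{f"n_{lab}": int(counts.get(lab, 0))
               for lab in sorted(labels.unique(), key=str)},
        })
    return pd.DataFrame(rows)


def freeman_halton_2xk(table) -> float:
    """Exact Fisher-Freeman-Halton p for a 2 x k contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed one
    (within a 1e-9 relative tolerance, the standard convention).
    """
    obs = np.asarray(table, int)
    if obs.shape[0] != 2:
        raise ValueError("table must have 2 rows")
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    n = obs.sum()

    def lfact(v):
        return lgamma(v + 1)

    const = sum(lfact(v) for v in r) + sum(lfact(v) for v in c) - lfact(n)

    def logp(row0):
        s = const
        for j, a in enumerate(row0):
            s -= lfact(a) + lfact(c[j] - a)
        return s

    lp_obs = logp(obs[0])
    total = 0.0
    ranges = [range(0, min(r[0], cj) + 1) for cj in c[:-1]]
    for combo in itertools.product(*ranges):
        last = r[0] - sum(combo)
        if last < 0 or last > c[-1]:
            continue
        lp = logp(list(combo) + [last])
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


def group_balance_tests(samples: pd.DataFrame) -> Dict:
    """Demographic balance across diagnostic groups.

    Fisher's exact test (Freeman-Halton for 2 x k) on sex x group counts,
    and one-way ANOVA on age with Tukey HSD pairwise comparisons.  Groups
    with fewer than two ages are excluded from the ANOVA with a warning.
    """
    groups = [g for g in samples["group"].unique()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sex_table = np.array([
        [int(((samples["group"] == g) & (samples["sex"] == s)).sum())
         for g in groups] for s in ("F", "M")])
    fisher_p = freeman_halton_2xk(sex_table)

    age_groups, kept = [], []
    for g in groups:
        ages = samples.loc[samples["group"] == g, "age"].to_numpy(float)
        if len(ages) < 2:
            warnings.warn(f"group {g} has < 2 ages; excluded from ANOVA")
            continue
        age_groups.append(ages)
        kept.append(g)
    f_stat, anova_p = stats.f_oneway(*age_groups)
    tk = stats.tukey_hsd(*age_groups)
    pairwise = {}
    for i, j in itertools.combinations(range(len(kept)), 2):
        pairwise[f"{kept[i]}_vs_{kept[j]}"] = float(tk.pvalue[i, j])
    return {
        "sex_groups": groups,
        "sex_table": sex_table.tolist(),
        "sex_fisher_p": fisher_p,
        "age_anova_F": float(f_stat),
        "age_anova_p": float(anova_p),
        "age_tukey_p": pairwise,
    }
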