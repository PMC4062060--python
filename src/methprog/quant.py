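"""Quantitative validation statistics: amplicon methylation aggregation,
Mann-Whitney tests, hierarchical clustering with multiscale-bootstrap support,
and PCA of M-value matrices.

Cluster support follows the multiscale bootstrap: for resampling scales r the
features are resampled with replacement at size round(r * n_features), the
bootstrap probability BP_r of each reference cluster is recorded, and the
approximately unbiased (AU) support comes from the two-parameter fit

    Phi^-1(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

by weighted least squares over scales with BP_r strictly inside (0, 1);
AU = 1 - Phi(v - c). BP at scale r = 1 is the ordinary bootstrap probability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.special import ndtr, ndtri

__all__ = [
    "AmpliconTable",
    "ClusterSupport",
    "PcaResult",
    "amplicon_means",
    "mann_whitney",
    "pairwise_distances",
    "hcluster",
    "tree_clusters",
    "cluster_support",
    "pca",
]

EXACT_MW_MAX = 8  # per-group size up to which the exact null is enumerated


@dataclass
class AmpliconTable:
    """Samples x CpG-unit methylation fractions with missingness.

    ``unit_amplicon`` maps each unit column to its amplicon; ``sample_group``
    maps each sample row to its group (disease stage, wildtype or standard).
    """

    values: pd.DataFrame
    unit_amplicon: pd.Series
    sample_group: pd.Series

    def __post_init__(self) -> None:
        v = self.values.values
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("methylation fractions must lie in [0, 1]")
        if set(self.values.columns) - set(self.unit_amplicon.index):
            raise ValueError("every unit must belong to exactly one amplicon")


def amplicon_means(table: AmpliconTable) -> pd.DataFrame:
    """Mean methylation per sample and amplicon over non-missing CpG units.

    Missing units are ignored; a sample/amplicon cell with no observed unit at
    all stays missing — nothing is imputed.
    """
    amp = table.unit_amplicon.loc[table.values.columns]
    return table.values.T.groupby(amp).mean().T


def mann_whitney(a, b, exact_max: int = EXACT_MW_MAX) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the rank-sum null when both groups have at most
    ``exact_max`` values and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if a.size <= exact_max and b.size <= exact_max and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def pairwise_distances(x: np.ndarray) -> np.ndarray:
    """Euclidean distances between sample rows with pairwise deletion.

    Missing features are excluded pairwise and the squared distance is rescaled
    by n_features / n_shared so magnitudes stay comparable across pairs with
    different missingness. A pair with no shared feature is an error.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    finite = np.isfinite(x)
    xz = np.where(finite, x, 0.0)
    w = finite.astype(float)
    shared = w @ w.T
    if np.any(shared[np.triu_indices(n, k=1)] == 0):
        i, j = np.argwhere(np.triu(shared == 0, k=1))[0]
        raise ValueError(f"samples {i} and {j} share no observed feature")
    sq = xz**2
    ssq = sq @ w.T
    d2 = ssq + ssq.T - 2.0 * (xz @ xz.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0) * (p / shared))
    np.fill_diagonal(d, 0.0)
    return d


def hcluster(x, metric: str = "euclidean", method: str = "average") -> np.ndarray:
    """Agglomerative clustering of sample rows; returns a scipy linkage matrix.

    Euclidean distance with pairwise deletion of missing features and average
    linkage by default, the combination used for methylation heatmaps.
    """
    if metric != "euclidean":
        raise ValueError("only euclidean distance is supported")
    arr = x.values if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    d = pairwise_distances(arr)
    condensed = d[np.triu_indices(arr.shape[0], k=1)]
    return linkage(condensed, method=method)


def tree_clusters(z: np.ndarray, n: int) -> list[frozenset]:
    """Leaf sets of the n-1 internal nodes of a linkage tree, in merge order."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (i, j) in enumerate(z[:, :2].astype(int)):
        merged = members[i] | members[j]
        members[n + k] = merged
        out.append(merged)
    return out


@dataclass
class ClusterSupport:
    """Dendrogram with bootstrap (BP) and approximately unbiased (AU) support."""

    linkage: np.ndarray
    labels: list
    nodes: list[frozenset]         # leaf-index sets, one per internal node
    bp: np.ndarray                 # ordinary bootstrap probability (scale r = 1)
    au: np.ndarray
    flags: list[str]               # "", "saturated", "absent" or "insufficient"
    bp_table: pd.DataFrame         # nodes x scales BP_r
    scales: np.ndarray
    B: int
    seed: int

    def node_labels(self) -> list[tuple]:
        return [tuple(sorted(self.labels[i] for i in node)) for node in self.nodes]


def fit_au(bp_row: np.ndarray, scales: np.ndarray, B: int) -> tuple[float, str]:
    """AU value for one node from its per-scale bootstrap probabilities.

    Weighted least squares of Phi^-1(1-BP_r) on (sqrt(r), 1/sqrt(r)) with
    binomial sampling weights; scales with BP_r in {0, 1} carry no information
    about the curve and are excluded. Fewer than three usable scales falls back
    to BP at r = 1 with a flag.
    """
    usable = (bp_row > 0) & (bp_row < 1)
    bp_at_1 = bp_row[np.argmin(np.abs(scales - 1.0))]
    if np.all(bp_row >= 1.0):
        return 1.0, "saturated"
    if np.all(bp_row <= 0.0):
        return 0.0, "absent"
    if usable.sum() < 3:
        return float(bp_at_1), "insufficient"
    r = scales[usable]
    bp = bp_row[usable]
    z = ndtri(1.0 - bp)
    wt = (B * stats.norm.pdf(z) ** 2) / (bp * (1.0 - bp))
    design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    wd = design * wt[:, None]
    coef = np.linalg.solve(design.T @ wd, wd.T @ z)
    v, c = coef
    return float(1.0 - ndtr(v - c)), ""


def cluster_support(
    x,
    B: int = 1000,
    scales: np.ndarray | None = None,
    seed: int = 0,
    method: str = "average",
) -> ClusterSupport:
    """Multiscale feature-bootstrap support for every cluster of a dendrogram."""
    if B < 100:
        raise ValueError("B must be at least 100")
    if scales is None:
        scales = np.linspace(0.5, 1.4, 10)
    scales = np.asarray(scales, dtype=float)
    if not np.any(np.isclose(scales, 1.0)):
        raise ValueError("scales must include r = 1 for the BP report")
    if isinstance(x, pd.DataFrame):
        labels = list(x.index)
        arr = x.values.astype(float)
    else:
        arr = np.asarray(x, dtype=float)
        labels = list(range(arr.shape[0]))
    n, p = arr.shape
    z = hcluster(arr, method=method)
    nodes = tree_clusters(z, n)
    rng = np.random.default_rng(seed)
    node_set = {node: i for i, node in enumerate(nodes)}
    bp_table = np.zeros((len(nodes), scales.size))
    for si, r in enumerate(scales):
        m = max(2, int(round(r * p)))
        for _ in range(B):
            cols = rng.integers(0, p, size=m)
            try:
                zb = hcluster(arr[:, cols], method=method)
            except ValueError:  # a pair lost all shared features in this resample
                continue
            for node in tree_clusters(zb, n):
                i = node_set.get(node)
                if i is not None:
                    bp_table[i, si] += 1
    bp_table /= B
    au = np.empty(len(nodes))
    flags = []
    for i in range(len(nodes)):
        au[i], flag = fit_au(bp_table[i], scales, B)
        flags.append(flag)
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    return ClusterSupport(
        linkage=z,
        labels=labels,
        nodes=nodes,
        bp=bp_table[:, r1].copy(),
        au=au,
        flags=flags,
        bp_table=pd.DataFrame(bp_table, columns=[f"r={r:.2f}" for r in scales]),
        scales=scales,
        B=B,
        seed=seed,
    )


@dataclass
class PcaResult:
    """Sample scores and per-component explained-variance fractions."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be non-negative and sum <= 1")


def pca(x, n_components: int | None = None) -> PcaResult:
    """PCA of samples x features via SVD of the feature-centered matrix.

    Missing values are an error (the caller imputes or drops). Component signs
    are fixed so the largest-magnitude score on each component is positive,
    making runs reproducible.
    """
    if isinstance(x, pd.DataFrame):
        labels = list(x.index)
        arr = x.values.astype(float)
    else:
        arr = np.asarray(x, dtype=float)
        labels = list(range(arr.shape[0]))
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(arr).all():
        raise ValueError("missing values not allowed; impute or drop first")
    centered = arr - arr.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    ratio = s**2 / total if total > 0 else np.zeros_like(s)
    scores = u * s
    for k in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, k])))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    if n_components is not None:
        scores = scores[:, :n_components]
        ratio = ratio[:n_components]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(pd.DataFrame(scores, index=labels, columns=cols), ratio)
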