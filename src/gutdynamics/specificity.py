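"""Organ-specific gene and peak identification.

Bulk features are quantile-normalized, log-transformed, and K-means
partitioned; clusters whose centroid is high in exactly one organ are
candidates, and features within them pass if their target-organ signal is
at least ``fold_min`` times the mean of the other organs (default 2.5).
Single-cell marker features use a rank-sum test with BH correction.
Overlap between peak sets is scored with a one-sided hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .genomics import PeakSet, overlaps_1bp

__all__ = [
    "NormalizedMatrix",
    "OrganSpecificSet",
    "quantile_normalize",
    "log2_transform",
    "depth_normalize",
    "select_high_dispersion_genes",
    "kmeans_partition",
    "call_organ_specific_features",
    "call_organ_specific_peaks",
    "call_organ_specific_genes",
    "call_marker_features_sc",
    "overlap_enrichment",
    "overlap_enrichment_grid",
]


@dataclass
class NormalizedMatrix:
    """Feature x sample values plus a tag recording the transform applied."""

    values: pd.DataFrame
    transform: str


@dataclass
class OrganSpecificSet:
    organ: str
    features: list[str]
    rule: dict = field(default_factory=dict)


def depth_normalize(counts: pd.DataFrame, target: float = 1e6) -> pd.DataFrame:
    """Scale each sample column to a common total of ``target``."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cannot depth-normalize a sample with zero total counts")
    return counts / totals * target


def quantile_normalize(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Force every sample column onto the cross-sample mean distribution.

    Each column's sorted values become the rank-wise means of the sorted
    columns; ties within a column receive the mean of their rank values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"column {matrix.columns[j]!r} is constant; tie rule applied")
        r = scipy.stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(r, np.arange(1, n + 1), ref)
    return NormalizedMatrix(
        pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        transform="quantile",
    )


def log2_transform(norm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    return NormalizedMatrix(
        np.log2(norm.values + pseudocount), transform=norm.transform + "+log"
    )


def select_high_dispersion_genes(norm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by index of dispersion (variance / mean) of log values.

    Genes whose mean is 0 are excluded.  Ranking ties break by identifier.
    """
    vals = norm.values
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=0)
    eligible = mean != 0
    disp = (var[eligible] / mean[eligible]).sort_index()
    if len(disp) < n:
        warnings.warn(f"only {len(disp)} eligible genes for requested {n}")
        n = len(disp)
    order = disp.sort_values(ascending=False, kind="mergesort")
    return order.index[:n].to_list()


def kmeans_partition(
    norm: NormalizedMatrix, k: int, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Deterministic K-means over feature rows; returns (labels, centroids, WCSS)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = norm.values.to_numpy(dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows < k={k}")
    km = KMeans(n_clusters=k, random_state=int(seed) % (2**31), n_init=10)
    labels = km.fit_predict(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=norm.values.columns)
    return (
        pd.Series(labels, index=norm.values.index, name="cluster"),
        centroids,
        float(km.inertia_),
    )


def call_organ_specific_features(
    signal: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    fold_min: float = 2.5,
    centroid_ratio: float = 2.0,
    row_standardize: bool = True,
) -> dict[str, OrganSpecificSet]:
    """Organ-specific features from a feature x organ normalized signal table.

    The table is quantile-normalized and log2(x+1)-transformed, and K-means
    partitions the features into ``k`` clusters (rows are z-scored first by
    default so clusters follow the cross-organ pattern rather than overall
    magnitude).  Clusters whose linear-scale centroid maximum is at least
    ``centroid_ratio`` times the second-highest organ are candidates for
    their argmax organ.  Candidate features pass if
    target / mean(other organs) >= ``fold_min`` on the quantile-normalized
    linear signal.  Per-organ sets are disjoint by construction.
    """
    if signal.shape[1] < 2:
        raise ValueError("need >= 2 organs")
    qn = quantile_normalize(signal)
    logm = log2_transform(qn)
    cluster_input = logm.values
    if row_standardize:
        mu = cluster_input.mean(axis=1)
        sd = cluster_input.std(axis=1, ddof=0).replace(0.0, 1.0)
        cluster_input = cluster_input.sub(mu, axis=0).div(sd, axis=0)
    labels, _, _ = kmeans_partition(
        NormalizedMatrix(cluster_input, logm.transform + "+rowz"), k=k, seed=seed
    )
    lin = qn.values
    organs = list(signal.columns)
    out = {o: OrganSpecificSet(o, [], {"fold_min": fold_min, "centroid_ratio": centroid_ratio})
           for o in organs}
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        centroid = lin.loc[members].mean(axis=0)
        ranked = centroid.sort_values(ascending=False)
        if len(ranked) < 2 or ranked.iloc[0] <= 0:
            continue
        if ranked.iloc[1] > 0 and ranked.iloc[0] < centroid_ratio * ranked.iloc[1]:
            continue
        organ = ranked.index[0]
        sub = lin.loc[members]
        others = [o for o in organs if o != organ]
        denom = sub[others].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = sub[organ] / denom
        fold[denom == 0] = np.inf
        passed = sub.index[fold >= fold_min]
        out[organ].features.extend(passed.to_list())
    return out


# the same contract applies to peaks and genes
call_organ_specific_peaks = call_organ_specific_features
call_organ_specific_genes = call_organ_specific_features


def call_marker_features_sc(
    matrix: pd.DataFrame,
    groups: pd.Series,
    target: str,
    fdr_max: float = 0.05,
    log2fc_min: float = 1.0,
    depth_target: float = 1e4,
) -> tuple[OrganSpecificSet, pd.DataFrame]:
    """Marker features of ``target`` cells versus all other cells.

    Per feature: a two-sided rank-sum (Mann-Whitney) test on depth-
    normalized counts, BH-adjusted across features; kept iff
    FDR <= fdr_max and log2 fold change >= log2fc_min.  Returns the call
    set and the full per-feature statistics table.
    """
    groups = groups.reindex(matrix.columns)
    in_grp = (groups == target).to_numpy()
    if in_grp.sum() < 2 or (~in_grp).sum() < 2:
        raise ValueError("each side of the comparison needs >= 2 cells")
    totals = matrix.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("cells with zero totals cannot be depth-normalized")
    norm = matrix.to_numpy(dtype=float) / totals[None, :] * depth_target
    x, y = norm[:, in_grp], norm[:, ~in_grp]
    if norm.shape[1] <= 20:
        # exact enumeration where feasible (hand-checkable at this size)
        from .temporal import rank_sum_p

        p = np.array([rank_sum_p(x[i], y[i]) for i in range(norm.shape[0])])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = scipy.stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(norm, axis=1) == 0
    p[constant] = 1.0
    fc = np.log2((x.mean(axis=1) + 1.0) / (y.mean(axis=1) + 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]
    stats = pd.DataFrame(
        {"log2fc": fc, "p": p, "fdr": fdr}, index=matrix.index
    )
    keep = stats.index[(stats["fdr"] <= fdr_max) & (stats["log2fc"] >= log2fc_min)]
    return (
        OrganSpecificSet(target, keep.to_list(), {"fdr_max": fdr_max, "log2fc_min": log2fc_min}),
        stats,
    )


# ---------------------------------------------------------------------------
# Overlap enrichment

def overlap_enrichment(
    set_a: PeakSet, set_b: PeakSet, universe: PeakSet
) -> tuple[float, int, int, int, int]:
    """One-sided hypergeometric overlap test of two peak sets in a universe.

    Membership is by >= 1 bp overlap with universe peaks.  Returns
    (p, overlap, |A|, |B|, N) with p = P(X >= overlap) for
    X ~ Hypergeom(N, |A|, |B|).
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    _, _, in_a = overlaps_1bp(set_a, universe)
    _, _, in_b = overlaps_1bp(set_b, universe)
    N = len(universe)
    K = int(in_a.sum())
    n = int(in_b.sum())
    obs = int((in_a & in_b).sum())
    p = float(scipy.stats.hypergeom.sf(obs - 1, N, K, n))
    return p, obs, K, n, N


def overlap_enrichment_grid(
    sets_a: dict[str, PeakSet],
    sets_b: dict[str, PeakSet],
    universe: PeakSet,
) -> pd.DataFrame:
    """All-pairs overlap enrichment with BH adjustment across the grid.

    Returns a long-format frame (organ_a, organ_b, overlap, p, p_adj,
    neglog10_padj).
    """
    rows = []
    for a_name, a in sets_a.items():
        for b_name, b in sets_b.items():
            p, obs, K, n, N = overlap_enrichment(a, b, universe)
            rows.append((a_name, b_name, obs, K, n, N, p))
    df = pd.DataFrame(
        rows, columns=["organ_a", "organ_b", "overlap", "size_a", "size_b", "universe", "p"]
    )
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        df["neglog10_padj"] = -np.log10(df["p_adj"])
    return df
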