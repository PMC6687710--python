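"""Consensus-clustering subtype discovery and centroid classification.

Subtypes are found by repeatedly clustering random subsamples of the most
variable features (median absolute deviation ranking), accumulating for
every sample pair the fraction of subsamples in which the pair landed in
the same cluster (the consensus matrix). The number of clusters k is
chosen by the CDF-area rule: the first k at which the area under the CDF
of consensus values grows by less than a threshold (default 10%)
relative to k-1.

Clustering is agglomerative with complete linkage on one-minus-Pearson
distances computed over pairwise-complete observations, matching the
common consensus-clustering configuration for tumor proteome matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def select_variable_features(matrix: pd.DataFrame, n: int = 1000) -> list[str]:
    """Top-n features by median absolute deviation (from the median).

    MAD is computed over non-missing values; features with fewer than 3
    non-missing values are excluded before ranking; ties are broken by
    feature id.
    """
    counts = matrix.notna().sum(axis=1)
    eligible = matrix.loc[counts >= 3]
    if n > len(eligible):
        raise ValueError(f"requested {n} features but only {len(eligible)} eligible")
    med = eligible.median(axis=1, skipna=True)
    mad = (eligible.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    ranked = mad.to_frame("mad").reset_index(names="feature")
    ranked = ranked.sort_values(["mad", "feature"], ascending=[False, True], kind="stable")
    return ranked["feature"].head(n).tolist()


def _pairwise_distance(matrix: pd.DataFrame) -> np.ndarray:
    """1 - Pearson between sample columns, pairwise-complete; undefined
    pairs are set to the largest finite distance (most dissimilar)."""
    corr = matrix.corr(method="pearson", min_periods=2)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    bad = ~np.isfinite(dist)
    if bad.any():
        finite_max = np.nanmax(np.where(np.isfinite(dist), dist, np.nan))
        warnings.warn(
            f"{int(bad.sum())} sample pairs had undefined correlation; "
            "distance set to the matrix maximum"
        )
        dist[bad] = finite_max
    return dist


def _cluster_labels(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    z = linkage(condensed, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def _cdf_area(values: np.ndarray) -> float:
    """Exact integral over [0, 1] of the empirical CDF of consensus values."""
    v = np.sort(np.clip(values, 0.0, 1.0))
    n = len(v)
    xs = np.concatenate([[0.0], v, [1.0]])
    heights = np.arange(0, n + 1) / n
    return float(np.sum(np.diff(xs) * heights))


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF areas, delta-areas and labels."""

    k_values: list[int]
    consensus: dict[int, pd.DataFrame]
    areas: dict[int, float]
    delta_area: dict[int, float]
    labels: dict[int, pd.Series]
    n_resamples: int
    chosen_k: int | None = None


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=range(2, 10),
    n_resamples: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    linkage_method: str = "complete",
    seed: int = 1234,
) -> ConsensusResult:
    """Consensus clustering of the sample columns of ``matrix``.

    Each resample draws ``ceil(p_item * n)`` samples without replacement
    (and, when ``p_feature < 1``, a feature subsample), clusters them
    hierarchically with ``linkage_method`` linkage on one-minus-Pearson
    distance, and counts co-clusterings. consensus(i, j) is the co-cluster
    count divided by the co-sample count; pairs never co-sampled get 0
    with a warning. Final per-k labels come from hierarchical clustering
    of one-minus-consensus.
    """
    k_values = sorted(k_range)
    if not k_values or len(k_values) < 1:
        raise ValueError("empty k_range")
    n = matrix.shape[1]
    if n < 2 * max(k_values):
        raise ValueError(
            f"need at least {2 * max(k_values)} samples for k up to {max(k_values)}"
        )
    if not (0.0 < p_item <= 1.0) or not (0.0 < p_feature <= 1.0):
        raise ValueError("p_item and p_feature must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    samples = list(matrix.columns)
    n_sub = int(np.ceil(p_item * n))

    full_dist = _pairwise_distance(matrix) if p_feature >= 1.0 else None
    co_cluster = {k: np.zeros((n, n)) for k in k_values}
    co_sampled = np.zeros((n, n))

    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        if full_dist is not None:
            dist = full_dist[np.ix_(idx, idx)]
        else:
            n_feat = int(np.ceil(p_feature * matrix.shape[0]))
            feat = rng.choice(matrix.shape[0], size=n_feat, replace=False)
            dist = _pairwise_distance(matrix.iloc[feat, idx])
        co_sampled[np.ix_(idx, idx)] += 1
        for k in k_values:
            labels = _cluster_labels(dist, k, linkage_method)
            for c in np.unique(labels):
                members = idx[labels == c]
                co_cluster[k][np.ix_(members, members)] += 1

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pairs were never co-sampled; "
            "their consensus is treated as 0"
        )

    consensus: dict[int, pd.DataFrame] = {}
    areas: dict[int, float] = {}
    labels_by_k: dict[int, pd.Series] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_values:
            m = np.where(co_sampled > 0, co_cluster[k] / co_sampled, 0.0)
            np.fill_diagonal(m, 1.0)
            m = (m + m.T) / 2.0
            cm = pd.DataFrame(m, index=samples, columns=samples)
            consensus[k] = cm
            iu = np.triu_indices(n, k=1)
            areas[k] = _cdf_area(m[iu])
            final = _cluster_labels(1.0 - m, k, linkage_method)
            labels_by_k[k] = pd.Series(final, index=samples, name=f"k{k}")

    delta: dict[int, float] = {}
    for i, k in enumerate(k_values):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[k_values[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    return ConsensusResult(
        k_values=k_values,
        consensus=consensus,
        areas=areas,
        delta_area=delta,
        labels=labels_by_k,
        n_resamples=n_resamples,
    )


def select_k(result: ConsensusResult, delta_threshold: float = 0.10) -> int:
    """First k whose relative CDF-area change versus k-1 is below the
    threshold; if never satisfied, the largest k with a warning."""
    if len(result.k_values) < 3:
        raise ValueError("need at least 3 k values to apply the CDF-area rule")
    for k in result.k_values[1:]:
        if result.delta_area[k] < delta_threshold:
            result.chosen_k = k
            return k
    warnings.warn(
        "CDF-area change never dropped below the threshold; returning max k"
    )
    result.chosen_k = result.k_values[-1]
    return result.chosen_k


def classify_by_centroids(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    min_shared: int = 10,
    unclassified: str = "unclassified",
) -> pd.Series:
    """Nearest-centroid classification by Pearson correlation.

    Each sample is labeled with the centroid column achieving the highest
    Pearson correlation over the genes shared between ``matrix`` and
    ``centroids`` (pairwise-complete). Samples with fewer than
    ``min_shared`` non-missing shared genes, or undefined correlations to
    every centroid, get the ``unclassified`` label. Ties break by centroid
    column order.
    """
    shared = matrix.index.intersection(centroids.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with the centroids; need {min_shared}"
        )
    x = matrix.loc[shared]
    c = centroids.loc[shared]
    out = {}
    for sample in x.columns:
        v = x[sample]
        ok = v.notna()
        if ok.sum() < min_shared:
            out[sample] = unclassified
            continue
        best, best_r = unclassified, -np.inf
        for label in c.columns:
            pair = pd.concat([v, c[label]], axis=1).dropna()
            if len(pair) < min_shared or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                continue
            r = pair.iloc[:, 0].corr(pair.iloc[:, 1])
            if np.isfinite(r) and r > best_r:
                best, best_r = label, r
        out[sample] = best
    return pd.Series(out, name="label")
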