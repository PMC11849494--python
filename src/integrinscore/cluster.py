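"""Resampling-based consensus clustering of samples on the signature transcriptome.

Follows the standard Monti scheme: repeatedly subsample the cohort, cluster each
subsample with k-means, and record for every sample pair how often they land in
the same cluster among the resamples where both were drawn.  The resulting
consensus matrix is partitioned by average-linkage hierarchical clustering on
1 - consensus, cut at k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

__all__ = ["ConsensusResult", "consensus_cluster", "adjusted_rand_index", "consensus_cdf"]


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame  # sample x sample, in [0, 1]
    labels: pd.Series  # sample -> cluster id (1..k)
    k: int
    n_resample: int
    item_consensus: pd.Series  # mean consensus of each sample with its cluster mates


def consensus_cluster(
    data,
    k: int,
    n_resample: int = 100,
    subsample_frac: float = 0.8,
    seed: int | None = 0,
) -> ConsensusResult:
    """Consensus k-means over ``n_resample`` subsamples of the rows of ``data``.

    ``data`` is samples x features (e.g. z-scored signature expression with
    samples as rows).  ``subsample_frac`` must lie in (0.5, 1]; consensus(i, j)
    is the co-assignment count over the co-sampling count, so any pair never
    co-sampled is an error (increase ``n_resample``).
    """
    if isinstance(data, pd.DataFrame):
        X = data.to_numpy(float)
        index = data.index
    else:
        X = np.asarray(data, float)
        index = pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct samples")
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} samples")
    if not 0.5 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must lie in (0.5, 1]")

    rng = np.random.default_rng(seed)
    m = max(k, int(round(subsample_frac * n)))
    co_sampled = np.zeros((n, n))
    co_assigned = np.zeros((n, n))
    for _ in range(n_resample):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(X[idx])
        sel = np.zeros(n, dtype=bool)
        sel[idx] = True
        co_sampled[np.ix_(idx, idx)] += 1.0
        same = lab[:, None] == lab[None, :]
        co_assigned[np.ix_(idx, idx)] += same

    if (co_sampled == 0).any():
        raise ValueError(
            "some sample pair was never co-sampled; increase n_resample or subsample_frac"
        )
    consensus = co_assigned / co_sampled
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")

    item = np.empty(n)
    for i in range(n):
        mates = (labels == labels[i]) & (np.arange(n) != i)
        item[i] = consensus[i, mates].mean() if mates.any() else 1.0

    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=index, columns=index),
        labels=pd.Series(labels, index=index, name="cluster"),
        k=k,
        n_resample=n_resample,
        item_consensus=pd.Series(item, index=index, name="item_consensus"),
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index; 1 iff identical partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(
            f"label vectors differ in length: {labels_a.size} vs {labels_b.size}"
        )
    return float(adjusted_rand_score(labels_a, labels_b))


def consensus_cdf(result: ConsensusResult, bins: int = 100) -> pd.DataFrame:
    """Empirical CDF of the off-diagonal consensus values (for choosing k)."""
    vals = squareform(result.consensus.to_numpy() - np.eye(len(result.consensus)), checks=False)
    grid = np.linspace(0, 1, bins + 1)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return pd.DataFrame({"consensus": grid, "cdf": cdf})
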