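"""Consensus clustering of stimulus-response profiles.

Cluster stability is assessed by repeated hierarchical clustering (Euclidean
distance, average linkage) of random 80% sample subsets; the consensus matrix
entry for a pair of samples is the fraction of co-sampled repetitions in
which they landed in the same cluster.  Final labels come from hierarchically
clustering ``1 - consensus`` as a distance.  The number of clusters is chosen
by the largest relative change in the area under the consensus CDF, the
standard criterion for this family of methods; the reported curve lets a user
override the choice.

Weak structure is flagged via the proportion of ambiguous clustering (PAC):
the fraction of off-diagonal consensus entries falling in the ambiguous
mid-range (0.1, 0.9) at the chosen k.  On clearly separable data the
consensus is near 0/1 and PAC is ~0; on structureless data most pairs
co-cluster sporadically and PAC is large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("stimscreen")


@dataclass
class ConsensusResult:
    k: int
    labels: pd.Series  # sample_id -> cluster id (1..k)
    consensus: pd.DataFrame  # samples x samples co-clustering fractions at chosen k
    areas: dict[int, float]  # k -> area under the consensus CDF
    deltas: dict[int, float]  # k -> relative change in area
    weak_structure: bool
    consensus_by_k: dict[int, np.ndarray] = field(repr=False, default_factory=dict)


def _cut_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, k, criterion="maxclust")


def _cdf_area(consensus: np.ndarray) -> float:
    # area under the empirical CDF of off-diagonal consensus values on [0, 1];
    # for value v the indicator contributes (1 - v) to the integral.
    iu = np.triu_indices(consensus.shape[0], k=1)
    return float(np.mean(1.0 - consensus[iu]))


def _pac(consensus: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus in (lo, hi)."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    return float(((vals > lo) & (vals < hi)).mean())


def select_k(areas: dict[int, float]):
    """Pick k maximising the relative change in consensus-CDF area.

    For the smallest candidate the area itself is the change (the usual
    convention).  Returns (k, deltas).
    """
    ks = sorted(areas)
    if not ks:
        raise ValueError("select_k needs at least one candidate k")
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    best = max(deltas, key=lambda k: deltas[k])
    return best, deltas


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=range(2, 8),
    n_reps: int = 10_000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    fixed_k: int | None = None,
) -> ConsensusResult:
    """Consensus clustering over ``n_reps`` random subsamples.

    Rows with missing values are dropped with a warning.  One linkage is
    computed per subsample and cut at every candidate k.  ``fixed_k`` skips
    model selection and reports that k (the selection curve is still
    computed).  Deterministic given the seed.
    """
    data = matrix.dropna(axis=0, how="any")
    if len(data) < len(matrix):
        logger.warning(
            "consensus_cluster: dropped %d sample(s) with missing values",
            len(matrix) - len(data),
        )
    n = len(data)
    ks = sorted(set(int(k) for k in k_range))
    if fixed_k is not None and fixed_k not in ks:
        ks = sorted(ks + [int(fixed_k)])
    if not ks or ks[0] < 2:
        raise ValueError("candidate k must be >= 2")
    if ks[-1] > n - 1:
        raise ValueError(f"k={ks[-1]} exceeds the {n} available samples")
    if n_reps < 1 or not 0 < subsample_frac <= 1:
        raise ValueError("need n_reps >= 1 and 0 < subsample_frac <= 1")

    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample_frac * n))
    X = data.to_numpy(dtype=float)
    cosampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        z = linkage(pdist(X[idx]), method="average")
        cosampled[np.ix_(idx, idx)] += 1
        for k in ks:
            labs = fcluster(z, k, criterion="maxclust")
            for c in np.unique(labs):
                grp = idx[labs == c]
                co_clustered[k][np.ix_(grp, grp)] += 1

    if np.any((cosampled == 0) & ~np.eye(n, dtype=bool)):
        logger.warning(
            "consensus_cluster: some sample pairs were never co-sampled; "
            "their consensus is reported as 0 (increase n_reps)"
        )
    denom = np.maximum(cosampled, 1)
    consensus_by_k = {k: co_clustered[k] / denom for k in ks}
    for k in ks:
        np.fill_diagonal(consensus_by_k[k], 1.0)

    areas = {k: _cdf_area(consensus_by_k[k]) for k in ks}
    chosen, deltas = select_k(areas)
    if fixed_k is not None:
        chosen = int(fixed_k)
    cons = consensus_by_k[chosen]
    weak = _pac(cons) > 0.2
    labels = pd.Series(
        _cut_labels(cons.copy(), chosen), index=data.index, name="cluster"
    )
    return ConsensusResult(
        k=chosen,
        labels=labels,
        consensus=pd.DataFrame(cons, index=data.index, columns=data.index),
        areas=areas,
        deltas=deltas,
        weak_structure=weak,
        consensus_by_k=consensus_by_k,
    )
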