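"""Consensus clustering: resampled co-clustering and cluster-number choice.

For each candidate k, samples are repeatedly subsampled and clustered;
the consensus matrix entry M_k(i, j) is the fraction of co-sampled
resamples in which i and j land in the same cluster. The area A(k)
under the empirical CDF of the consensus values summarises how binary
(stable) the matrix is, and the relative increase Delta(k) guides the
choice of k.

Raw Delta(k) values are not comparable across k — a structureless
Gaussian cloud already yields Delta(3) around 0.3 from unstable
splits, and planted two-group data keeps Delta(4) well above zero
because every spurious sub-split still rides on the sharp true split.
The number of clusters is therefore chosen by the proportion of
ambiguous clustering: PAC(k) is the fraction of consensus entries
falling strictly between 0.05 and 0.95, i.e. sample pairs whose
co-clustering is unstable under resampling. The chosen k is the
largest one with PAC at or below ``pac_threshold``; when no k
qualifies the partition is flagged low-confidence and the smallest
candidate k is used. A(k) and Delta(k) are
still computed and reported as diagnostics. Final labels come from
average-linkage hierarchical clustering of the consensus dissimilarity
1 - M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix

LOW_CONFIDENCE_MEAN = 0.8
PAC_LOWER, PAC_UPPER = 0.05, 0.95


@dataclass
class ConsensusResult:
    """Consensus matrices over a k range and the selected partition."""

    consensus_matrices: dict        # k -> samples x samples ndarray
    auc: dict                       # k -> A(k)
    delta_auc: dict                 # k -> Delta(k)
    pac: dict                       # k -> proportion of ambiguous clustering
    chosen_k: int
    labels: pd.Series               # final partition at chosen_k (0-based)
    resamples: int
    sample_fraction: float
    seed: int
    low_confidence: bool = False    # no k reached the PAC threshold


def _area_under_cdf(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values on [0, 1]."""
    xs = np.sort(values)
    uniq, counts = np.unique(xs, return_counts=True)
    cdf = np.cumsum(counts) / len(xs)
    grid = np.concatenate((uniq, [1.0]))
    area = uniq[0] * 0.0
    total = 0.0
    for i in range(len(uniq)):
        width = grid[i + 1] - grid[i]
        total += width * cdf[i]
    return float(total)


def _consensus_pass(X: np.ndarray, k_range, resamples, sample_fraction,
                    inner_restarts, rng):
    """One full resampling pass: consensus matrices, A(k), Delta(k), PAC(k)."""
    n = X.shape[0]
    m = int(np.ceil(sample_fraction * n))
    subsets = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(resamples)]
    co_sampled = np.zeros((n, n))
    for idx in subsets:
        co_sampled[np.ix_(idx, idx)] += 1
    if (co_sampled[np.triu_indices(n, 1)] == 0).any():
        raise ValueError("some sample pair was never co-sampled; "
                         "increase resamples or sample_fraction")
    consensus, auc, pac = {}, {}, {}
    iu = np.triu_indices(n, 1)
    for k in k_range:
        together = np.zeros((n, n))
        for idx in subsets:
            rs = int(rng.integers(2 ** 31 - 1))
            labels = KMeans(n_clusters=k, n_init=inner_restarts,
                            random_state=rs).fit_predict(X[idx])
            same = labels[:, None] == labels[None, :]
            together[np.ix_(idx, idx)] += same
        M = together / co_sampled
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        vals = M[iu]
        auc[k] = _area_under_cdf(vals)
        pac[k] = float(((vals > PAC_LOWER) & (vals < PAC_UPPER)).mean())
    delta = {}
    ks = sorted(auc)
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = auc[k]
        else:
            prev = auc[ks[i - 1]]
            delta[k] = (auc[k] - prev) / prev if prev > 0 else np.inf
    return consensus, auc, delta, pac


def consensus_cluster(matrix: ExpressionMatrix, genes=None, k_range=range(2, 7),
                      resamples: int = 100, sample_fraction: float = 0.8,
                      seed: int = 0, pac_threshold: float = 0.1,
                      inner_restarts: int = 4) -> ConsensusResult:
    """Consensus clustering of the samples on a gene subset.

    Per resample, ceil(f * n) samples are drawn without replacement and
    k-means is run on the (unweighted) feature subset. A pair that is
    never co-sampled is an error (raise B or f). The number of clusters
    is the largest k whose PAC is at or below ``pac_threshold``.
    """
    if genes is not None:
        matrix = matrix.subset_genes(genes)
        if matrix.n_genes == 0:
            raise ValueError("gene subset is empty or absent from the matrix")
    X = matrix.samples_by_genes()
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    n = X.shape[0]
    k_range = [int(k) for k in k_range if 2 <= k <= n]
    if not k_range:
        raise ValueError("k_range contains no feasible k")
    if resamples < 10:
        raise ValueError("resamples must be >= 10")
    if not (0.5 <= sample_fraction <= 1.0):
        raise ValueError("sample_fraction must be in [0.5, 1]")

    rng = np.random.default_rng(seed)
    consensus, auc, delta, pac = _consensus_pass(X, k_range, resamples,
                                                 sample_fraction, inner_restarts, rng)

    ks = sorted(auc)
    iu = np.triu_indices(n, 1)
    eligible = [k for k in ks if pac[k] <= pac_threshold]
    if eligible:
        chosen_k = max(eligible)
        low_conf = False
    else:
        # no stable k: fall back to the smallest candidate, flagged
        chosen_k = ks[0]
        low_conf = True

    M = consensus[chosen_k]
    Z = linkage(squareform(1.0 - M, checks=False), method="average")
    raw = fcluster(Z, t=chosen_k, criterion="maxclust")
    # relabel clusters by order of first appearance for determinism
    remap, labels = {}, []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        labels.append(remap[r])
    # mean within-cluster consensus: a second, label-aware structure check
    within = [M[np.ix_(np.flatnonzero(np.array(labels) == c),
                       np.flatnonzero(np.array(labels) == c))]
              for c in range(chosen_k)]
    within_vals = [w[np.triu_indices(len(w), 1)].mean() for w in within if len(w) > 1]
    within_mean = float(np.mean(within_vals)) if within_vals else 1.0
    return ConsensusResult(
        consensus_matrices=consensus,
        auc=auc,
        delta_auc=delta,
        pac=pac,
        chosen_k=chosen_k,
        labels=pd.Series(labels, index=matrix.samples),
        resamples=resamples,
        sample_fraction=sample_fraction,
        seed=seed,
        low_confidence=low_conf or within_mean < LOW_CONFIDENCE_MEAN,
    )
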