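"""Sparse k-means with L1/L2-constrained feature weights.

Clustering and gene selection are performed jointly: maximize the
weighted between-cluster sum of squares

    sum_j w_j * BCSS_j(labels)   s.t.  ||w||_2 <= 1, ||w||_1 <= s, w >= 0

by alternating (i) k-means on the sqrt(w)-scaled features and (ii) the
closed-form weight update, a soft-thresholding of the per-gene BCSS
with the threshold set by bisection so that the L1 bound is met with
equality. The L1 bound ``s`` controls how many genes get a strictly
positive weight — the "relevant genes" of a classification round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix

MAX_ITER = 50
REL_TOL = 1e-6
# a gene is "selected" when its weight is a non-negligible fraction of
# the largest weight; the strictly-positive support is discontinuous in
# s near the L1 saturation point (arbitrarily many vanishing weights
# enter at once), while weights above this floor carry essentially all
# of the clustering signal
REL_WEIGHT_FLOOR = 0.05


@dataclass
class SparseKMeansFit:
    """One fitted sparse k-means solution."""

    weights: pd.Series          # per-gene w_j >= 0, ||w||_2 <= 1, ||w||_1 <= s
    labels: pd.Series           # per-sample cluster in 0..k-1
    objective: float            # sum_j w_j * BCSS_j
    sparsity_bound: float
    n_restarts: int
    seed: int
    degenerate: bool = False    # zero BCSS everywhere (no structure to weight)

    @property
    def selected_genes(self) -> list:
        """Genes whose weight clears the relative floor (see REL_WEIGHT_FLOOR)."""
        w = self.weights.to_numpy()
        if w.max() <= 0:
            return []
        return list(self.weights.index[w > REL_WEIGHT_FLOOR * w.max()])


def _per_feature_bcss(X: np.ndarray, labels: np.ndarray, tot_ss: np.ndarray) -> np.ndarray:
    """BCSS_j = total SS_j - within SS_j, per feature; X is samples x genes."""
    wcss = np.zeros(X.shape[1])
    for c in np.unique(labels):
        block = X[labels == c]
        wcss += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    return np.maximum(tot_ss - wcss, 0.0)


def _weight_vector(bcss: np.ndarray, s: float) -> np.ndarray:
    """argmax_w w.bcss subject to ||w||_2 <= 1, ||w||_1 <= s, w >= 0."""
    if not np.any(bcss > 0):
        return np.zeros_like(bcss)

    def w_of(delta: float) -> np.ndarray:
        st = np.maximum(bcss - delta, 0.0)
        norm = np.linalg.norm(st)
        return st / norm if norm > 0 else st

    w = w_of(0.0)
    if w.sum() <= s + 1e-12:
        return w
    lo, hi = 0.0, float(bcss.max())
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if w_of(mid).sum() > s:
            lo = mid
        else:
            hi = mid
    w = w_of(hi)
    if w.max() == 0.0:
        # exactly tied top values: the soft-threshold path cannot reach
        # the L1 bound; the limit solution concentrates on one argmax
        w = np.zeros_like(bcss)
        w[int(np.argmax(bcss))] = 1.0
    return w


def sparse_kmeans(matrix: ExpressionMatrix, k: int, s: float,
                  n_restarts: int = 5, seed: int = 0,
                  max_iter: int = MAX_ITER, init_labels=None) -> SparseKMeansFit:
    """Fit sparse k-means; best of ``n_restarts`` by objective.

    Deterministic for a given seed. The alternation is a monotone
    ascent on the objective (asserted in-loop); it stops on a relative
    objective change below 1e-6 or after ``max_iter`` rounds.
    ``init_labels`` warm-starts the first restart from a given
    partition (used by the tuning path).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n_samples:
        raise ValueError("k cannot exceed the number of samples")
    X = matrix.samples_by_genes()
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    p = X.shape[1]
    if not (1.0 <= s <= np.sqrt(p) + 1e-9):
        raise ValueError("s must satisfy 1 <= s <= sqrt(n_genes)")
    tot_ss = ((X - X.mean(axis=0)) ** 2).sum(axis=0)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        rs = int(rng.integers(2 ** 31 - 1))
        w = np.full(p, 1.0 / np.sqrt(p))
        if restart == 0 and init_labels is not None:
            labels = np.asarray(init_labels, dtype=int)
            if len(np.unique(labels)) != k:
                raise ValueError("init_labels must use exactly k clusters")
        else:
            km = KMeans(n_clusters=k, n_init=1, random_state=rs)
            labels = km.fit_predict(X * np.sqrt(w))
        objective = -np.inf
        degenerate = False
        for _ in range(max_iter):
            bcss = _per_feature_bcss(X, labels, tot_ss)
            if not np.any(bcss > 0):
                w = np.zeros(p)
                objective = 0.0
                degenerate = True
                break
            w = _weight_vector(bcss, s)
            new_objective = float(w @ bcss)
            assert new_objective >= objective - 1e-8 * max(1.0, abs(objective)), \
                "objective must not decrease across iterations"
            if objective > 0 and (new_objective - objective) / objective < REL_TOL:
                objective = new_objective
                break
            objective = new_objective
            # warm-started k-means step in the re-weighted space
            Z = X * np.sqrt(w)
            centers = np.vstack([Z[labels == c].mean(axis=0) if np.any(labels == c)
                                 else Z[rng.integers(len(Z))]
                                 for c in range(k)])
            km = KMeans(n_clusters=k, n_init=1, init=centers, max_iter=100)
            labels = km.fit_predict(Z)
        if best is None or objective > best[0]:
            best = (objective, w.copy(), labels.copy(), degenerate)

    objective, w, labels, degenerate = best
    assert np.linalg.norm(w) <= 1 + 1e-9 and w.sum() <= s + 1e-9 and (w >= 0).all()
    return SparseKMeansFit(
        weights=pd.Series(w, index=matrix.genes),
        labels=pd.Series(labels, index=matrix.samples),
        objective=max(objective, 0.0),
        sparsity_bound=s,
        n_restarts=n_restarts,
        seed=seed,
        degenerate=degenerate,
    )


def tune_sparsity(matrix: ExpressionMatrix, k: int, s_grid=None,
                  n_permutations: int = 4, seed: int = 0,
                  n_restarts: int = 1, refine: bool = True):
    """Pick the L1 bound by the permutation gap statistic.

    gap(s) = log(objective on data) - mean log(objective on matrices
    with every gene row independently permuted across samples). The
    returned ``s`` is the argmax (ties to the smaller s). With
    ``refine`` a second, finer grid is evaluated between the coarse
    argmax's neighbours: the informative-gene count responds to ``s``
    only on a narrow interval near sqrt(block size), which a coarse
    geometric grid cannot resolve.

    Returns ``(chosen_s, table)`` where table has columns (s, gap,
    objective, n_selected).
    """
    p = matrix.n_genes
    if s_grid is None:
        s_grid = np.geomspace(1.2, max(np.sqrt(p), 1.3), num=8)
    s_grid = sorted(float(s) for s in s_grid)
    if not s_grid:
        raise ValueError("s_grid must be non-empty")
    rng = np.random.default_rng(seed)
    X = matrix.samples_by_genes()

    datasets = [matrix]
    for _ in range(n_permutations):
        Xp = np.empty_like(X)
        for j in range(X.shape[1]):
            Xp[:, j] = X[rng.permutation(X.shape[0]), j]
        datasets.append(ExpressionMatrix(pd.DataFrame(
            Xp.T, index=matrix.genes, columns=matrix.samples)))

    # warm-started path: fit each dataset over the grid from the
    # largest s (dense, easy to optimize) downwards, initializing every
    # fit from the previous partition; keeps single-restart fits on the
    # same ascent path and the gap curve smooth across s
    chains = [None] * len(datasets)
    rows: dict = {}

    def evaluate(grid, seed_offset):
        for i, s in enumerate(sorted(set(grid) - set(rows), reverse=True)):
            logs = []
            for di, data in enumerate(datasets):
                top = chains[di] is None     # diversify the top-of-chain fit
                fit = sparse_kmeans(data, k, s,
                                    n_restarts=max(n_restarts, 4) if top else n_restarts,
                                    seed=seed + 1000 + seed_offset + 17 * di + i,
                                    init_labels=chains[di])
                chains[di] = fit.labels.to_numpy()
                logs.append((np.log(max(fit.objective, 1e-12)), fit))
            log_obj, fit = logs[0]
            null = float(np.mean([lg for lg, _ in logs[1:]])) if n_permutations else 0.0
            rows[s] = (s, log_obj - null, fit.objective, len(fit.selected_genes))

    evaluate(s_grid, 0)
    if refine and len(s_grid) > 1:
        coarse = [rows[s] for s in sorted(rows)]
        gaps = [r[1] for r in coarse]
        i_best = int(np.argmax(gaps))
        svals = sorted(rows)
        lo = svals[max(i_best - 1, 0)]
        hi = svals[min(i_best + 1, len(svals) - 1)]
        if hi > lo:
            fine = [s for s in np.geomspace(lo, hi, num=9)[1:-1]
                    if 1.0 <= s <= np.sqrt(p)]
            evaluate(fine, 500)

    table = pd.DataFrame([rows[s] for s in sorted(rows)],
                         columns=["s", "gap", "objective", "n_selected"])
    best = table.loc[table["gap"].idxmax()]
    # ties -> smaller s
    ties = table[np.isclose(table["gap"], best["gap"], rtol=0, atol=1e-12)]
    chosen = float(ties["s"].min())
    return chosen, table
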