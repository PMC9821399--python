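"""Significance Analysis of Microarrays (SAM) with permutation FDR.

Per gene the moderated statistic is d_i = r_i / (s_i + s0): a group
contrast r_i over a pooled standard error s_i, regularized by the
exchangeability constant s0 so that genes with tiny variance cannot
dominate. Two classes use the signed difference of group means with
the two-sample pooled SE; k > 2 classes use the standard multiclass
SAM contrast

    r_i = sqrt( (n / prod_g n_g) * sum_g n_g (xbar_ig - xbar_i)^2 )

with s_i = sqrt(pooled_var_i * sum_g 1/n_g), which reduces to the
absolute two-sample t numerator/denominator at k = 2. The null
distribution of d comes from label permutations; the FDR at a
threshold delta is the median number of permuted |d| values beyond
delta divided by the observed call count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

S0_PERCENTILE_GRID = np.arange(0.0, 1.0001, 0.05)
N_S0_WINDOWS = 100


@dataclass
class SAMResult:
    """Per-gene SAM statistics and the permutation FDR table."""

    d: pd.Series
    r: pd.Series
    s: pd.Series
    s0: float
    delta: float
    fdr_table: pd.DataFrame        # columns: delta, called, median_false, fdr
    significant_genes: list
    n_permutations: int
    seed: int
    excluded_genes: list = field(default_factory=list)


def _group_stats(X: np.ndarray, labels: np.ndarray):
    """Signed two-class or multiclass SAM contrast and pooled SE per gene."""
    classes, counts = np.unique(labels, return_counts=True)
    n = X.shape[1]
    means = np.stack([X[:, labels == c].mean(axis=1) for c in classes], axis=1)
    ss_within = np.zeros(X.shape[0])
    for c in classes:
        block = X[:, labels == c]
        ss_within += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss_within / (n - len(classes))
    if len(classes) == 2:
        r = means[:, 1] - means[:, 0]
        s = np.sqrt(pooled_var * (1.0 / counts[0] + 1.0 / counts[1]))
    else:
        xbar = X.mean(axis=1)
        between = (counts[None, :] * (means - xbar[:, None]) ** 2).sum(axis=1)
        fac = n / np.prod(counts.astype(float))
        r = np.sqrt(fac * between)
        s = np.sqrt(pooled_var * (1.0 / counts).sum())
    return r, s


def estimate_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Original SAM rule: s0 minimizing the coefficient of variation of
    the spread of d across windows of s."""
    edges = np.unique(np.quantile(s, np.linspace(0, 1, N_S0_WINDOWS + 1)))
    if len(edges) < 3:
        return float(np.median(s))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    cvs = []
    candidates = [float(np.quantile(s, q)) for q in S0_PERCENTILE_GRID]
    for s0 in candidates:
        d = r / (s + s0)
        mads = []
        for wi in range(len(edges) - 1):
            vals = d[window == wi]
            if len(vals) > 1:
                mads.append(np.median(np.abs(vals - np.median(vals))) * 1.4826)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() <= 0:
            cvs.append(np.inf)
            continue
        cvs.append(mads.std(ddof=1) / mads.mean())
    return candidates[int(np.argmin(cvs))]


def _calls_at(abs_d: np.ndarray, delta: float) -> int:
    return int((abs_d >= delta).sum())


def sam(matrix: ExpressionMatrix, labels, n_permutations: int = 200,
        s0_method: str = "cv-min", delta: float | None = None,
        fdr_target: float | None = None, seed: int = 0,
        s0_value: float | None = None) -> SAMResult:
    """Run SAM on a complete matrix against a k-level grouping.

    Exactly one of ``delta`` (an explicit threshold on |d|) or
    ``fdr_target`` (pick the smallest delta whose estimated FDR is at
    or below the target) should be given; with neither, delta defaults
    to the value reaching FDR <= 0.05. ``s0_value`` overrides the s0
    estimation (s0 = 0 recovers the plain t statistic at k = 2).
    """
    labels = np.asarray(labels)
    X = matrix.to_array()
    if np.isnan(X).any():
        raise ValueError("SAM requires a complete matrix")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if delta is None and fdr_target is None:
        fdr_target = 0.05

    genes = np.array(matrix.genes)
    r, s = _group_stats(X, labels)
    if s0_value is not None:
        s0 = float(s0_value)
    elif s0_method == "cv-min":
        s0 = estimate_s0(r, s)
    elif s0_method == "median":
        s0 = float(np.median(s))
    else:
        raise ValueError(f"unknown s0_method {s0_method!r}")

    keep = (s + s0) > 0
    excluded = [str(g) for g in genes[~keep]]
    genes, X, r, s = genes[keep], X[keep], r[keep], s[keep]
    d = r / (s + s0)
    abs_d = np.abs(d)

    rng = np.random.default_rng(seed)
    null_abs = np.empty((n_permutations, len(d)))
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        rp, sp = _group_stats(X, perm)
        null_abs[b] = np.abs(rp / (sp + s0))

    # FDR table over a grid of candidate thresholds
    grid = np.unique(np.concatenate(([0.0], np.quantile(abs_d, np.linspace(0, 1, 101)),
                                     [abs_d.max() + 1e-9])))
    rows = []
    for dlt in grid:
        called = _calls_at(abs_d, dlt)
        false = float(np.median((null_abs >= dlt).sum(axis=1)))
        fdr = min(false / called, 1.0) if called > 0 else 0.0
        rows.append((float(dlt), called, false, fdr))
    fdr_table = pd.DataFrame(rows, columns=["delta", "called", "median_false", "fdr"])

    if delta is None:
        ok = fdr_table[fdr_table["fdr"] <= fdr_target]
        delta = float(ok["delta"].min()) if not ok.empty else float(abs_d.max() + 1e-9)
    significant = [str(g) for g in genes[abs_d >= delta]]

    return SAMResult(
        d=pd.Series(d, index=genes),
        r=pd.Series(r, index=genes),
        s=pd.Series(s, index=genes),
        s0=float(s0),
        delta=float(delta),
        fdr_table=fdr_table,
        significant_genes=significant,
        n_permutations=n_permutations,
        seed=seed,
        excluded_genes=excluded,
    )
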