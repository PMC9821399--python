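"""Recursive informative-layer extraction.

Each round couples gene selection with sample classification: sparse
k-means picks the genes that currently carry the strongest clustering
signal, consensus clustering fixes the number of groups and the final
partition on those genes, and enrichment names the layer. The selected
genes are then removed and the next round runs on the remainder, so
successive layers are built from disjoint gene sets and can carry
independent information (immune vs molecular, in the tumor setting).
Extraction stops when a layer has no enriched function, when its
classification merely repeats an earlier layer's (adjusted Rand index
above the redundancy threshold), or at ``max_layers``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .consensus import ConsensusResult, consensus_cluster
from .enrich import WITHOUT_FUNCTION, enrich_main_function
from .expression import ExpressionMatrix
from .sparse_kmeans import sparse_kmeans, tune_sparsity

REDUNDANCY_ARI = 0.7
MIN_WORKING_GENES = 10


@dataclass
class Layer:
    """One extraction round: its genes, weights and classification."""

    index: int
    genes: list
    weights: pd.Series
    classification: ConsensusResult
    main_function: str = WITHOUT_FUNCTION
    redundant_with: int | None = None

    @property
    def labels(self) -> pd.Series:
        return self.classification.labels

    @property
    def k(self) -> int:
        return self.classification.chosen_k


def layer_similarity(a: Layer, b: Layer) -> float:
    """Adjusted Rand index between two layers' classifications."""
    if list(a.labels.index) != list(b.labels.index):
        raise ValueError("layers must classify the same samples")
    return float(adjusted_rand_score(a.labels.to_numpy(), b.labels.to_numpy()))


def extract_layers(matrix: ExpressionMatrix, k_range=range(2, 7),
                   max_layers: int = 10, annotation: dict | None = None,
                   stop_policy: str = "function_or_redundant", seed: int = 0,
                   resamples: int = 100, sample_fraction: float = 0.8,
                   n_permutations: int = 4, redundancy_threshold: float = REDUNDANCY_ARI,
                   n_restarts: int = 5) -> list[Layer]:
    """Run the recursive sparse k-means / consensus clustering loop.

    Per round: tune the sparsity bound at the smallest candidate k, fit
    sparse k-means, classify the selected genes by consensus
    clustering; if consensus chooses a different k, refit sparse
    k-means once at that k and re-classify (single iteration). The
    layer's genes are removed before the next round.

    ``stop_policy``: "function_or_redundant" stops after the first
    layer with no enriched function or a redundant classification;
    "max_layers" only stops at the round cap or gene exhaustion.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    if stop_policy not in ("function_or_redundant", "max_layers"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    annotation = annotation or {}
    background = list(matrix.genes)
    k_range = sorted(int(k) for k in k_range)

    working = matrix.copy()
    layers: list[Layer] = []
    for round_index in range(1, max_layers + 1):
        if working.n_genes < max(MIN_WORKING_GENES, max(k_range)):
            break
        round_seed = seed + 10_000 * round_index
        k0 = k_range[0]
        s, _ = tune_sparsity(working, k0, n_permutations=n_permutations,
                             seed=round_seed)
        fit = sparse_kmeans(working, k0, s, n_restarts=n_restarts, seed=round_seed + 1)
        genes = fit.selected_genes
        if not genes or fit.degenerate:
            break
        cc = consensus_cluster(working, genes, k_range=k_range, resamples=resamples,
                               sample_fraction=sample_fraction, seed=round_seed + 2)
        if cc.chosen_k != k0:
            refit = sparse_kmeans(working, cc.chosen_k, s, n_restarts=n_restarts,
                                  seed=round_seed + 3)
            if refit.selected_genes and not refit.degenerate:
                fit, genes = refit, refit.selected_genes
                cc = consensus_cluster(working, genes, k_range=k_range,
                                       resamples=resamples,
                                       sample_fraction=sample_fraction,
                                       seed=round_seed + 4)
        label, _, _ = enrich_main_function(genes, annotation, background)
        layer = Layer(
            index=round_index,
            genes=sorted(genes),
            weights=fit.weights.loc[sorted(genes)],
            classification=cc,
            main_function=label,
        )
        for earlier in layers:
            if layer_similarity(layer, earlier) >= redundancy_threshold:
                layer.redundant_with = earlier.index
                break
        layers.append(layer)
        working = working.drop_genes(genes)
        if stop_policy == "function_or_redundant" and (
                layer.main_function == WITHOUT_FUNCTION or layer.redundant_with is not None):
            break
    return layers


def merge_layers(layers, matrix: ExpressionMatrix, k_range=range(2, 7),
                 seed: int = 0, resamples: int = 100,
                 sample_fraction: float = 0.8) -> ConsensusResult:
    """Re-classify samples on the union of several layers' gene sets.

    Used to collapse partially overlapping molecular layers into a
    single classification over their combined genes.
    """
    layers = list(layers)
    if len(layers) < 2:
        raise ValueError("merge_layers needs at least 2 layers")
    union: list = []
    for layer in layers:
        union.extend(layer.genes)
    if len(set(union)) != len(union):
        raise ValueError("layer gene sets must be disjoint")
    return consensus_cluster(matrix, union, k_range=k_range, resamples=resamples,
                             sample_fraction=sample_fraction, seed=seed)
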