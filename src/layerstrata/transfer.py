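"""Applying a discovery-cohort layer classification to a new cohort.

The transfer uses only the layer's gene identities: the new cohort is
re-classified from scratch by consensus clustering on the genes the
layer selected that are also measured in the new cohort. Genes missing
from the new platform are reported, never imputed. Because the new
classification is fit fresh, its group labels are arbitrary; an
optional centroid-correlation alignment to the discovery groups is
reported but not silently applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusResult, consensus_cluster
from .expression import ExpressionMatrix
from .layers import Layer

MIN_SHARED_GENES = 5


@dataclass
class TransferReport:
    """Outcome of transferring one layer to a new cohort."""

    layer_index: int
    genes_used: list
    genes_missing: list
    classification: ConsensusResult
    k_discovery: int
    k_new: int
    group_alignment: dict | None = None   # new group -> best-matching discovery group

    @property
    def k_agreement(self) -> bool:
        return self.k_discovery == self.k_new


def align_groups(new_matrix: ExpressionMatrix, new_labels: pd.Series,
                 discovery_matrix: ExpressionMatrix, discovery_labels: pd.Series,
                 genes) -> dict:
    """Match new groups to discovery groups by centroid correlation.

    Centroids are mean expression over the shared genes; each new group
    is assigned the discovery group whose centroid correlates best.
    """
    genes = [g for g in genes if g in new_matrix.genes and g in discovery_matrix.genes]
    if len(genes) < 2:
        raise ValueError("need at least 2 shared genes for alignment")
    new_vals = new_matrix.values.loc[genes]
    disc_vals = discovery_matrix.values.loc[genes]
    mapping = {}
    for g_new in sorted(new_labels.unique()):
        cen_new = new_vals.loc[:, new_labels[new_labels == g_new].index].mean(axis=1)
        best, best_r = None, -np.inf
        for g_disc in sorted(discovery_labels.unique()):
            cen_disc = disc_vals.loc[:, discovery_labels[discovery_labels == g_disc].index].mean(axis=1)
            r = float(np.corrcoef(cen_new, cen_disc)[0, 1])
            if r > best_r:
                best, best_r = g_disc, r
        mapping[int(g_new)] = int(best)
    return mapping


def transfer_classification(new_matrix: ExpressionMatrix, layer: Layer,
                            k_range=range(2, 7), seed: int = 0,
                            min_genes: int = MIN_SHARED_GENES,
                            resamples: int = 100, sample_fraction: float = 0.8,
                            discovery_matrix: ExpressionMatrix | None = None) -> TransferReport:
    """Re-classify a new cohort on a discovery layer's genes.

    Pure function of the new matrix, the gene list and the seed: no
    discovery-cohort statistics enter the clustering.
    """
    present = set(new_matrix.genes)
    genes_used = sorted(g for g in layer.genes if g in present)
    genes_missing = sorted(g for g in layer.genes if g not in present)
    if len(genes_used) < min_genes:
        raise ValueError(
            f"only {len(genes_used)} of layer {layer.index}'s genes are in the new "
            f"cohort (floor {min_genes}); missing: {genes_missing[:10]}")
    cc = consensus_cluster(new_matrix, genes_used, k_range=k_range,
                           resamples=resamples, sample_fraction=sample_fraction,
                           seed=seed)
    alignment = None
    if discovery_matrix is not None:
        alignment = align_groups(new_matrix, cc.labels, discovery_matrix,
                                 layer.labels, genes_used)
    return TransferReport(
        layer_index=layer.index,
        genes_used=genes_used,
        genes_missing=genes_missing,
        classification=cc,
        k_discovery=layer.k,
        k_new=cc.chosen_k,
        group_alignment=alignment,
    )
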