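"""Local annotation-term enrichment for network branches and layers.

Replaces interactive ontology lookups with a one-sided hypergeometric
overrepresentation test over a user-supplied term -> gene-set map (GMT
style), against an explicit background universe. The term with the
smallest p-value names the branch ("main function"); a branch whose
genes overlap no term at all is labelled "Without function".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

WITHOUT_FUNCTION = "Without function"


@dataclass
class FunctionalNode:
    """A branch of the gene network with its enriched main function."""

    name: str
    genes: list
    main_function: str = WITHOUT_FUNCTION
    annotated_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.annotated_genes) <= set(self.genes):
            raise ValueError("annotated_genes must be a subset of genes")


def enrichment_table(genes, annotation: dict, background) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each term in ``genes``.

    Returns a table (term, overlap, term_size, p, q) sorted by
    (p, -overlap, term), with Benjamini-Hochberg q-values.
    """
    genes = set(genes)
    background = set(background)
    if not genes <= background:
        raise ValueError("background must contain all query genes")
    M = len(background)
    N = len(genes)
    rows = []
    for term, term_genes in annotation.items():
        term_set = set(term_genes) & background
        n = len(term_set)
        k = len(genes & term_set)
        if n == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append((term, k, n, p))
    if not rows:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "q"])
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    table["q"] = stats.false_discovery_control(table["p"].to_numpy(), method="bh")
    table = table.sort_values(["p", "overlap", "term"],
                              ascending=[True, False, True]).reset_index(drop=True)
    return table


def enrich_main_function(genes, annotation: dict, background) -> tuple[str, float, pd.DataFrame]:
    """Main-function label of a gene set: the smallest-p overlapping term.

    Ties go to the larger overlap, then the lexicographically smaller
    term. With no overlapping term (or an empty annotation) the label
    is "Without function" with p = 1.
    """
    table = enrichment_table(genes, annotation, background)
    overlapping = table[table["overlap"] > 0]
    if overlapping.empty:
        return WITHOUT_FUNCTION, 1.0, table
    best = overlapping.iloc[0]
    return str(best["term"]), float(best["p"]), table


def annotate_branches(branches, annotation: dict, background) -> list[FunctionalNode]:
    """Wrap branch gene sets as FunctionalNodes with enrichment labels."""
    nodes = []
    for i, genes in enumerate(branches, start=1):
        label, _, _ = enrich_main_function(genes, annotation, background)
        if label == WITHOUT_FUNCTION:
            annotated = []
        else:
            annotated = sorted(set(genes) & set(annotation[label]))
        nodes.append(FunctionalNode(name=f"branch{i}", genes=sorted(genes),
                                    main_function=label, annotated_genes=annotated))
    return nodes
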