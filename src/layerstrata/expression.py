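"""Gene-by-sample expression container.

The analysis substrate is a genes x samples matrix of log2 expression
values. Missing cells (unobserved values, or zeros converted at log2
time in count mode) are carried as NaN; ``missing_mask`` exposes them
explicitly. Gene symbols and sample IDs must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes as rows and samples as columns.

    ``values`` is a float DataFrame; NaN marks a missing cell.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")

    # -- basic views ---------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing."""
        return self.values.isna()

    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    # -- subsetting ----------------------------------------------------
    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes].copy())

    def drop_genes(self, genes) -> "ExpressionMatrix":
        drop = set(genes)
        keep = [g for g in self.values.index if g not in drop]
        return ExpressionMatrix(self.values.loc[keep].copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)].copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy())

    # -- numpy views ---------------------------------------------------
    def to_array(self) -> np.ndarray:
        """genes x samples float array (NaN where missing)."""
        return self.values.to_numpy(dtype=float)

    def samples_by_genes(self) -> np.ndarray:
        """samples x genes float array, the clustering orientation."""
        return self.values.to_numpy(dtype=float).T
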