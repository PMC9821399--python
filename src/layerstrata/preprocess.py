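"""Preprocessing recipes producing the analysis-ready log2 matrix.

Two recipes are supported, mirroring how public tumor RNA-seq
compendia and small capture-sequencing cohorts are typically prepared:

* ``tcga`` mode — start from a log2-scale expression table: optional
  official-symbol allow-list, valid-fraction gene filter, downshifted
  normal imputation of missing values, selection of the most variable
  genes by standard deviation.
* ``counts`` mode — start from a raw count table: merge duplicated
  gene symbols by summation, minimum-total-count filter, log2
  transform with zeros converted to missing, zero-fraction filter,
  then the same imputation.

Each stage is a pure function of its input, its configuration and (for
imputation) a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class PreprocessConfig:
    """Knobs of both recipes with the defaults used throughout.

    valid_fraction : minimum fraction of observed values a gene needs
        to be kept (tcga mode).
    top_n : number of most-variable genes retained at the end.
    min_total_counts : minimum total count across samples (counts mode).
    max_zero_fraction : genes with a strictly larger missing fraction
        after log2 are removed (counts mode).
    impute_width : SD of imputed values as a fraction of the per-sample
        observed SD.
    impute_downshift : number of per-sample SDs subtracted from the
        per-sample observed mean to centre the imputation distribution.
    """

    valid_fraction: float = 0.75
    top_n: int = 2000
    min_total_counts: float = 400
    max_zero_fraction: float = 0.5
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.valid_fraction <= 1):
            raise ValueError("valid_fraction must be in (0, 1]")
        if self.top_n < 2:
            raise ValueError("top_n must be >= 2")
        for name in ("min_total_counts", "max_zero_fraction", "impute_width", "impute_downshift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------
# count-table stages
# ---------------------------------------------------------------------

def merge_duplicate_symbols(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene symbols by summing their rows per sample."""
    for gene in raw_table.index[~raw_table.apply(
            lambda r: pd.to_numeric(r, errors="coerce").notna().all(), axis=1)]:
        raise ValueError(f"non-numeric values in row for gene {gene!r}")
    table = raw_table.astype(float)
    if not table.index.has_duplicates:
        return table.copy()
    out = table.groupby(level=0, sort=False).sum()
    return out


def filter_min_total_counts(counts: pd.DataFrame, min_total_counts: float) -> pd.DataFrame:
    """Keep genes whose total count across samples is >= the threshold."""
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if counts.empty:
        return counts.copy()
    totals = counts.sum(axis=1)
    return counts.loc[totals >= min_total_counts].copy()


def log2_transform(counts: pd.DataFrame) -> ExpressionMatrix:
    """log2 of positive entries; zeros become missing cells (no pseudocount)."""
    counts = counts.astype(float)
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative input to log2_transform")
    with np.errstate(divide="ignore"):
        out = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    return ExpressionMatrix(pd.DataFrame(out, index=counts.index, columns=counts.columns))


# ---------------------------------------------------------------------
# matrix stages
# ---------------------------------------------------------------------

def filter_zero_fraction(matrix: ExpressionMatrix, max_zero_fraction: float) -> ExpressionMatrix:
    """Remove genes whose missing fraction is strictly above the threshold."""
    frac = matrix.missing_mask.mean(axis=1)
    keep = frac[frac <= max_zero_fraction].index
    return matrix.subset_genes(keep)


def filter_valid_fraction(matrix: ExpressionMatrix, valid_fraction: float) -> ExpressionMatrix:
    """Keep genes observed in at least ``valid_fraction`` of samples."""
    frac = 1.0 - matrix.missing_mask.mean(axis=1)
    keep = frac[frac >= valid_fraction].index
    return matrix.subset_genes(keep)


def filter_official_symbols(matrix: ExpressionMatrix, allow_list) -> ExpressionMatrix:
    """Restrict to genes on an allow-list (e.g. official symbols)."""
    allow = set(allow_list)
    return matrix.subset_genes([g for g in matrix.genes if g in allow])


def impute_downshifted_normal(matrix: ExpressionMatrix, impute_width: float = 0.3,
                              impute_downshift: float = 1.8, seed: int = 0) -> ExpressionMatrix:
    """Impute missing cells from a downshifted per-sample normal.

    For sample column j with observed mean m_j and SD s_j, missing
    cells are drawn from N(m_j - downshift * s_j, (width * s_j)^2).
    Observed cells are never altered.
    """
    values = matrix.values.copy()
    rng = np.random.default_rng(seed)
    for sample in values.columns:
        col = values[sample]
        observed = col.dropna()
        n_missing = int(col.isna().sum())
        if len(observed) < 2 and n_missing > 0:
            raise ValueError(f"sample {sample!r} has fewer than 2 observed values")
        if n_missing == 0:
            continue
        m = float(observed.mean())
        s = float(observed.std(ddof=1))
        draws = rng.normal(m - impute_downshift * s, impute_width * s, size=n_missing)
        values.loc[col.isna(), sample] = draws
    return ExpressionMatrix(values)


def select_top_variable(matrix: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Retain the ``top_n`` genes with largest SD (ties by gene symbol).

    The original gene order is preserved within the selection.
    """
    if not matrix.is_complete():
        raise ValueError("select_top_variable requires a complete matrix (impute first)")
    sd = matrix.values.std(axis=1, ddof=1)
    order = sorted(matrix.genes, key=lambda g: (-sd[g], g))
    chosen = set(order[: min(top_n, matrix.n_genes)])
    keep = [g for g in matrix.genes if g in chosen]
    return matrix.subset_genes(keep)


# ---------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------

def preprocess_tcga(matrix: ExpressionMatrix, config: PreprocessConfig,
                    allow_list=None) -> ExpressionMatrix:
    """Symbol filter -> valid-fraction filter -> impute -> top-N by SD.

    The input is expected on log2 scale already (with NaN for missing).
    """
    out = matrix
    if allow_list is not None:
        out = filter_official_symbols(out, allow_list)
    out = filter_valid_fraction(out, config.valid_fraction)
    out = impute_downshifted_normal(out, config.impute_width, config.impute_downshift,
                                    seed=config.seed)
    out = select_top_variable(out, config.top_n)
    return out


def preprocess_counts(counts: pd.DataFrame, config: PreprocessConfig) -> ExpressionMatrix:
    """Merge duplicates -> min-counts filter -> log2 -> zero filter -> impute."""
    table = merge_duplicate_symbols(counts)
    table = filter_min_total_counts(table, config.min_total_counts)
    matrix = log2_transform(table)
    matrix = filter_zero_fraction(matrix, config.max_zero_fraction)
    matrix = impute_downshifted_normal(matrix, config.impute_width, config.impute_downshift,
                                       seed=config.seed)
    return matrix
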