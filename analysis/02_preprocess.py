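"""Produce the analysis-ready log2 matrices.

Applies the compendium-style recipe to both cohorts: keep genes with at
least 75% observed values, impute the rest from a downshifted normal
(1.8 SD below, 0.3 SD wide, per sample), keep the 2000 most variable
genes by SD.
"""

from pathlib import Path

from layerstrata import PreprocessConfig, preprocess_tcga
from layerstrata import io as lio

DATA = Path("scratch/data")
SEED = 20260920


def main() -> None:
    for i, name in enumerate(("discovery", "validation")):
        raw = lio.read_expression_tsv(DATA / f"{name}_expression.tsv")
        cfg = PreprocessConfig(valid_fraction=0.75, top_n=2000, seed=SEED + 10 + i)
        matrix = preprocess_tcga(raw, cfg)
        lio.write_expression_tsv(matrix, DATA / f"{name}_preprocessed.tsv")
        print(f"{name}: {raw.n_genes} -> {matrix.n_genes} genes after "
              f"valid-fraction filter, imputation and top-SD selection")


if __name__ == "__main__":
    main()
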