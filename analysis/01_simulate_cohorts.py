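"""Generate the synthetic discovery and validation cohorts.

Plants two independent informative layers in a 2000-gene expression
matrix — a two-group "immune-like" layer (150 genes) and a three-group
"molecular-like" layer (200 genes) — plus survival times whose hazard
depends only on the immune-like factor (HR 4 between its groups).
A second, independent 300-sample cohort from the same generator serves
as the validation series for classification transfer.
"""

from pathlib import Path

from layerstrata import LayerSpec, SurvivalLinkSpec, generate_dataset
from layerstrata import io as lio

OUT = Path("scratch/data")
SEED = 20260920

SPECS = [
    LayerSpec("immune", 150, 2, (0.5, 0.5), 2.0, 1.0),
    LayerSpec("molecular", 200, 3, (1 / 3, 1 / 3, 1 / 3), 2.0, 1.0),
]
LINK = SurvivalLinkSpec("immune", baseline_hazard=0.05,
                        hr_per_group=(1.0, 4.0), censor_time=8.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, n, seed in (("discovery", 300, SEED), ("validation", 300, SEED + 1)):
        ds = generate_dataset(SPECS, n, 1650, survival=LINK,
                              missing_rate=0.02, seed=seed)
        lio.write_expression_tsv(ds.expression, OUT / f"{name}_expression.tsv")
        ds.truth_labels.to_csv(OUT / f"{name}_truth_labels.tsv", sep="\t",
                               index_label="sample")
        lio.write_gmt(ds.truth_gene_sets, OUT / f"{name}_truth_gene_sets.gmt")
        lio.write_survival_tsv(ds.survival, OUT / f"{name}_survival.tsv")
        print(f"{name}: {ds.expression.n_genes} genes x {ds.expression.n_samples} "
              f"samples, {int(ds.survival['event'].sum())} events")


if __name__ == "__main__":
    main()
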