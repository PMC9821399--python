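"""Differential expression across layer groups and survival stratification.

Runs multiclass SAM on the three-group layer's genes against its own
classification, then Kaplan-Meier / log-rank / Mantel-Haenszel HR for
the immune-like layer groups, whose planted hazard ratio is 4.
"""

from pathlib import Path

import pandas as pd

from layerstrata import hazard_ratio, km_by_group, logrank_test, sam
from layerstrata import io as lio

DATA = Path("scratch/data")
LAYERS = Path("results/layers")
OUT = Path("results/stats")
SEED = 20260920


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = lio.read_expression_tsv(DATA / "discovery_preprocessed.tsv")
    labels = pd.read_csv(LAYERS / "layer_labels.tsv", sep="\t", index_col="sample")
    summary = pd.read_csv(LAYERS / "layer_summary.tsv", sep="\t")
    layer_sets = lio.read_gmt(LAYERS / "layers.gmt")
    survival = lio.read_survival_tsv(DATA / "discovery_survival.tsv")

    # SAM across the groups of the layer with the most groups
    target = summary.loc[summary["k"].idxmax()]
    name = f"layer{int(target['layer'])}"
    genes = layer_sets[name]
    res = sam(matrix.subset_genes(genes), labels[name].loc[matrix.samples],
              n_permutations=200, fdr_target=0.05, seed=SEED + 40)
    report = pd.DataFrame({"gene": res.d.index, "d": res.d.to_numpy(),
                           "significant": [g in set(res.significant_genes)
                                           for g in res.d.index]})
    report.to_csv(OUT / "sam_molecular_groups.tsv", sep="\t", index=False)
    print(f"SAM on {name} ({int(target['k'])} groups): "
          f"{len(res.significant_genes)} of {len(genes)} genes called "
          f"at FDR 0.05 (s0 = {res.s0:.3f})")

    # survival by the two-group layer's classification
    target = summary[summary["k"] == 2].iloc[0]
    name = f"layer{int(target['layer'])}"
    records = survival.copy()
    records["group"] = labels[name].loc[records["sample"]].to_numpy()
    parts = [sub[["time", "event"]] for _, sub in records.groupby("group")]
    lr = logrank_test(parts)
    hr = hazard_ratio(parts[1], parts[0])
    curves = km_by_group(records)
    km_rows = []
    for g, km in curves.items():
        for t, n, d, s in zip(km.times, km.at_risk, km.events, km.survival):
            km_rows.append((g, t, n, d, s))
    pd.DataFrame(km_rows, columns=["group", "time", "at_risk", "events",
                                   "survival"]).to_csv(
        OUT / "km_by_immune_group.tsv", sep="\t", index=False)
    pd.DataFrame([(name, lr.chi2, lr.p, hr.hr, hr.ci_low, hr.ci_high)],
                 columns=["layer", "chi2", "p", "hr", "ci_low", "ci_high"]).to_csv(
        OUT / "survival_by_immune_group.tsv", sep="\t", index=False)
    print(f"log-rank on {name}: chi2 = {lr.chi2:.1f}, p = {lr.p:.2e}; "
          f"MH HR = {hr.hr:.2f} [{hr.ci_low:.2f}, {hr.ci_high:.2f}]")


if __name__ == "__main__":
    main()
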