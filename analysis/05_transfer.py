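"""Transfer the discovery layer classifications to the validation cohort.

Re-classifies the validation samples by a fresh consensus clustering on
each layer's genes and checks group-count agreement and recovery of the
planted labels.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from layerstrata import ConsensusResult, Layer, transfer_classification
from layerstrata import io as lio

DATA = Path("scratch/data")
LAYERS = Path("results/layers")
OUT = Path("results/transfer")
SEED = 20260920


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    new_matrix = lio.read_expression_tsv(DATA / "validation_preprocessed.tsv")
    truth = pd.read_csv(DATA / "validation_truth_labels.tsv", sep="\t",
                        index_col="sample")
    layer_sets = lio.read_gmt(LAYERS / "layers.gmt")
    disc_labels = pd.read_csv(LAYERS / "layer_labels.tsv", sep="\t",
                              index_col="sample")

    rows = []
    for i, (name, genes) in enumerate(sorted(layer_sets.items())):
        present = set(genes) & set(new_matrix.genes)
        if len(present) < 5:
            print(f"{name}: only {len(present)} genes measured in the "
                  f"validation cohort; skipped")
            continue
        k_disc = int(disc_labels[name].nunique())
        cc = ConsensusResult(consensus_matrices={}, auc={}, delta_auc={}, pac={},
                             chosen_k=k_disc, labels=disc_labels[name],
                             resamples=100, sample_fraction=0.8, seed=0)
        layer = Layer(index=i + 1, genes=sorted(genes),
                      weights=pd.Series(1.0, index=sorted(genes)),
                      classification=cc)
        report = transfer_classification(new_matrix, layer, seed=SEED + 30 + i)
        lio.write_labels_tsv(report.classification.labels,
                             OUT / f"{name}_labels.tsv", layer=name)
        aris = {col: adjusted_rand_score(report.classification.labels, truth[col])
                for col in truth.columns}
        best = max(aris, key=aris.get)
        rows.append((name, k_disc, report.k_new, len(report.genes_used),
                     len(report.genes_missing), best, round(aris[best], 3)))
    summary = pd.DataFrame(rows, columns=["layer", "k_discovery", "k_new",
                                          "genes_used", "genes_missing",
                                          "best_truth_match", "ari"])
    summary.to_csv(OUT / "transfer_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
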