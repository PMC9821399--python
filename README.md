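# layerstrata

Separating the independent **informative layers** of a tumor
transcriptome. Bulk expression of a tumor mixes signals of different
origin: immune infiltration writes one signature across the genes,
tumor-intrinsic programs (melanogenesis, keratinization, extracellular
matrix) write others. `layerstrata` recovers these layers one at a
time and shows that they classify the same patients in mutually
independent ways — the immune layer carrying prognosis and (in the
motivating melanoma setting) response to anti-PD1 therapy, while the
molecular layers carry tissue-program information with no survival
signal.

The workflow, for computational biologists working with gene-by-sample
matrices:

1. **Preprocess** — valid-value filtering, downshifted-normal
   imputation of missing values, top-2000 genes by SD (or the
   count-data variant: symbol merging, ≥400-count filter, log2 with
   zeros as missing, ≤50%-zero filter).
2. **Network** — a decomposable Gaussian graphical model over the
   genes: the Chow-Liu maximum-likelihood spanning tree
   (MI = −½ ln(1 − r²)), then a forward search adding the edge with the
   most negative ΔBIC = n ln(1 − r²_{uv·S}) + ln n among
   chordality-preserving candidates; branches split by edge
   betweenness, named by hypergeometric enrichment, summarised as
   functional-node activities (mean log2 expression of the annotated
   genes).
3. **Layer extraction** — sparse k-means (maximize Σ w_j·BCSS_j with
   ‖w‖₂ ≤ 1, ‖w‖₁ ≤ s, w ≥ 0; s tuned by a permutation gap statistic)
   selects the genes driving the strongest classification; consensus
   clustering (resampled co-clustering, number of groups by the PAC
   criterion) fixes the partition; the genes are removed and the loop
   repeats, yielding disjoint layers.
4. **Transfer** — a layer's gene set re-classifies an independent
   cohort by a fresh consensus clustering.
5. **Statistics** — multiclass SAM (d = r/(s + s0), permutation FDR),
   Kaplan–Meier curves, log-rank tests, Mantel–Haenszel hazard ratios.

Real cohorts of this kind sit behind read-mapping pipelines, so the
package ships a synthetic-cohort generator (`layerstrata.simulate`)
that plants independent layers and a survival link with known ground
truth; all tests and the analysis are exercised against it. See
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from layerstrata import (LayerSpec, SurvivalLinkSpec, generate_dataset,
                         extract_layers, hazard_ratio, logrank_test)

specs = [LayerSpec("immune", 150, 2, (0.5, 0.5), effect=2.0, within_sd=1.0),
         LayerSpec("molecular", 200, 3, (1/3, 1/3, 1/3), 2.0, 1.0)]
link = SurvivalLinkSpec("immune", baseline_hazard=0.05,
                        hr_per_group=(1.0, 4.0), censor_time=8.0)
ds = generate_dataset(specs, n_samples=300, n_noise_genes=1650,
                      survival=link, seed=0)
ann = {f"{k}_term": v for k, v in ds.truth_gene_sets.items()}
layers = extract_layers(ds.expression, annotation=ann, seed=0)
for ly in layers:
    print(ly.index, ly.main_function, ly.k, len(ly.genes))
```

prints

```
1 immune_term 2 150
2 molecular_term 3 200
3 Without function 2 8
```

— round one finds the 150-gene immune-like block and splits the
samples in two, round two finds the molecular block and splits them in
three, round three selects nothing meaningful ("Without function") and
stops. The same run continues into survival:

```python
sv = ds.survival
g1 = sv[sv["group"] == 1][["time", "event"]]
g0 = sv[sv["group"] == 0][["time", "event"]]
print(round(logrank_test([g0, g1]).p, 30), round(hazard_ratio(g1, g0).hr, 2))
```

```
5.65293369242e-19 4.74
```

— the immune-layer groups separate survival decisively, with the
Mantel–Haenszel estimate near the planted hazard ratio of 4.

The end-to-end narrative lives in `analysis/01_simulate_cohorts.py`
… `analysis/06_differential_and_survival.py`; each script states what
it found and writes its tables under `results/` (bulky intermediate
cohort matrices go to `scratch/`, regenerated on each run). The
`layerstrata.pipeline` module runs the same stages as one orchestrated,
seed-deterministic unit with a checksum manifest.

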