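# Methods

`layerstrata` implements a workflow for separating the independent
"informative layers" of a bulk tumor transcriptome — in melanoma, an
immune layer (infiltration state, predictive of response to anti-PD1
therapy and prognostic for survival) and tumor-intrinsic molecular
layers (melanogenesis, keratinization, extracellular matrix). Because
the real cohorts (a TCGA-scale RNA-seq compendium and a small clinical
capture-sequencing series) require an upstream read-mapping pipeline,
the package ships a synthetic-cohort generator with planted ground
truth, and every claim its tests make is a claim about recovery of
that planted structure.

## Synthetic cohorts

`generate_dataset` draws a log2-scale expression matrix of
`sum(n_genes) + n_noise_genes` genes by `n_samples` samples. Each
`LayerSpec` plants a disjoint block of informative genes driven by its
own categorical latent factor, drawn i.i.d. per sample from the
spec's `proportions` and independent across layers. Gene `i` of a
layer has value

    mu_i + offset(z_layer(sample)) + N(0, within_sd^2),

with baseline means `mu_i ~ N(8, 2^2)` (the typical log2 FPKM range of
tumor RNA-seq; the downshifted-normal imputation behaves realistically
against this scale) and group offsets equally spaced on
`[-effect/2, +effect/2]` so a gene's overall mean does not depend on
the group proportions. Noise genes have group-independent means.
Missingness is completely at random at `missing_rate`.

Reference conditions used throughout tests and the acceptance script:
two layers of 150 genes (k = 2, balanced) and 200 genes (k = 3,
balanced), `effect = 2.0`, `within_sd = 1.0`, 1650 noise genes, 300
samples. An `effect` of 2.0 log2 units with unit residual SD is a
strong but realistic class signature (a two-fold expression difference
per gene between extreme groups).

Survival: `SurvivalLinkSpec` attaches exponential survival times with
hazard `baseline_hazard * hr_per_group[z]` depending only on the
driving layer's factor, with administrative censoring at
`censor_time`. Reference design: baseline hazard 0.05 events per time
unit, HR 4, censoring at 8 time units (roughly 1/3 of baseline-group
subjects have events — the event fraction of a clinical melanoma
series with short follow-up). This censoring level matters: the
Mantel-Haenszel O/E-ratio estimator attenuates large hazard ratios
when nearly all subjects fail (with no censoring a true HR of 4 is
estimated near 2.95); at the reference design the estimate is ~3.9.

`count_mode` converts the log2 matrix to Poisson counts with
per-sample library-size normalization and optional excess zeros,
for exercising the count-data preprocessing recipe.

What the generator does **not** emulate: batch effects, tumor purity,
gene-gene correlation beyond the layer factors, mutation subtypes,
library-composition artifacts, non-exponential hazards. Passing tests
show the machinery recovers clean planted structure; they do not show
how it degrades on real cohorts with correlated nuisance structure.

## Preprocessing

Two recipes, each a pure function of input + config + seed:

* compendium ("tcga") mode: optional official-symbol allow-list →
  keep genes with ≥ 75% observed values (`valid_fraction`) →
  downshifted-normal imputation → top 2000 genes by SD (`top_n`; ties
  broken on the gene symbol, SD uses denominator n−1).
* count mode: sum duplicated symbols → keep genes with total counts ≥
  400 (`min_total_counts`) → log2 with zeros treated as missing (no
  pseudocount, since imputation follows the zero filter) → drop genes
  with strictly more than 50% missing → imputation.

Imputation draws each missing cell of sample `j` from
`N(m_j − 1.8 s_j, (0.3 s_j)^2)` where `m_j, s_j` are the observed
per-sample mean and SD — the documented defaults of the proteomics
convention this mimics (width 0.3, downshift 1.8, per column).
Observed cells are never altered.

## Decomposable Gaussian graphical model

The gene network is a chordal (decomposable) Gaussian Markov network
learned in two steps:

1. **Chow-Liu tree.** Maximum spanning tree under Gaussian mutual
   information `MI = −½ ln(1 − r²)`; Kruskal with lexicographic
   tie-break, so the tree is deterministic.
2. **Forward BIC search.** Greedily add the admissible edge with the
   most negative `ΔBIC = n ln(1 − r²_{uv·S}) + ln n`, where `S` is the
   minimal u–v separator and `r_{uv·S}` the partial correlation given
   `S`; stop when no candidate improves BIC or at `max_added_edges`.
   Admissible candidates are enumerated from the junction tree: two
   maximal cliques can be made adjacent in some junction tree iff
   their intersection size equals the minimum separator weight on the
   junction-tree path between them, and joining `u ∈ Ci\S` to
   `v ∈ Cj\S` then preserves chordality with new clique `S ∪ {u,v}`.
   This avoids any per-candidate chordality test; tests verify the
   enumeration against brute-force try-and-check and verify that the
   incremental ΔBIC equals full BIC recomputation to 1e-8.

The model log-likelihood factorizes over cliques and separators
(MLE covariance, denominator n); `df = 2·n_nodes + n_edges` (a mean
and variance per gene plus one parameter per edge).

Branch splitting removes the highest edge-betweenness edge
(lexicographic tie-break) until the target component count is reached;
the branch count is a configuration parameter, not model-selected.
Branches are named by one-sided hypergeometric enrichment against a
user-supplied term → gene-set map with Benjamini–Hochberg q-values; a
branch overlapping no term is labelled "Without function". A
functional node's activity is the plain mean log2 expression of its
main-function-annotated genes (a flag switches to all branch genes);
activities are compared between groups with Mann-Whitney (exact for
tie-free n ≤ 12) or Kruskal-Wallis.

## Sparse k-means and the sparsity bound

Gene selection and clustering are joint: maximize
`Σ_j w_j·BCSS_j` subject to `‖w‖₂ ≤ 1, ‖w‖₁ ≤ s, w ≥ 0`, alternating
k-means on `sqrt(w)`-scaled features with the closed-form
soft-threshold weight update (threshold set by bisection so the L1
bound binds). The k-means step is warm-started from the previous
partition's centers, making the alternation a monotone ascent
(asserted in-loop); the best of `n_restarts` seeded restarts is kept.

The bound `s` is tuned by the permutation gap statistic
`gap(s) = log O(s) − mean_b log O_b(s)` over matrices with each gene
row independently permuted. Two implementation details matter in
practice:

* **Path evaluation.** Across the `s` grid each dataset is fitted from
  the largest `s` downwards, warm-starting every fit from the previous
  partition (with extra restarts only at the top of the chain).
  Independent single-restart fits produce objective noise across `s`
  that swamps the gap curve.
* **Grid refinement.** The number of selected genes responds to `s`
  only on a narrow interval near `sqrt(block size)`, so after the
  coarse geometric grid a finer grid is evaluated between the
  neighbours of the coarse argmax.

Selected genes are those with weight above 5% of the maximum weight.
The strictly-positive support is discontinuous in `s`: just above the
L1 saturation point, thousands of genes enter with weights two orders
of magnitude below the signal genes, while the relative floor keeps
the selected set stable and equal to the planted block on reference
data.

## Consensus clustering and the number of groups

For each candidate k (default 2–6), `resamples = 100` subsamples of
80% of samples are clustered by k-means (4 inner restarts); the
consensus matrix entry is the co-clustering frequency among co-sampled
pairs. The CDF area A(k) and its relative change Δ(k) are reported as
diagnostics, but the number of groups is chosen by PAC — the
proportion of consensus entries strictly between 0.05 and 0.95
(ambiguously co-clustered pairs): the chosen k is the largest with
PAC ≤ 0.1. Calibration on planted structures showed why Δ(k) alone
cannot decide: true two-group data keeps Δ(3) ≈ 0.25 and Δ(4) ≈ 0.16
(every spurious sub-split rides on the sharp true split), while a
structureless cloud already reaches Δ(3) ≈ 0.33. PAC returns k = 2, 3,
3, 2 on planted k=2, planted k=3, three separated blobs, and a single
blob respectively; when no k reaches the threshold the smallest
candidate is used and the result is flagged low-confidence. Final
labels come from average-linkage hierarchical clustering of 1 − M.

## Recursive layer extraction

Per round: tune `s` at the smallest candidate k, fit sparse k-means,
classify the selected genes by consensus clustering; if consensus
chooses a different k, refit sparse k-means once at that k (same `s`)
and re-classify — one iteration, mirroring the ambiguity of whether
selection precedes or follows the choice of k. The layer is named by
enrichment, compared to earlier layers by adjusted Rand index
(redundant at ARI ≥ 0.7), and its genes are removed from the working
matrix. Extraction stops at the first unannotated or redundant layer
(policy "function_or_redundant"), at `max_layers` (default 10), or on
gene exhaustion. Layers judged to carry the same kind of information
can be merged: `merge_layers` re-runs consensus clustering on the
union of their (disjoint) gene sets.

## Transfer, SAM, survival

* **Transfer** uses only the layer's gene identities: a fresh
  consensus clustering on the intersection of layer genes with the new
  cohort (floor: 5 shared genes; missing genes are reported, never
  imputed). Because the clustering is fit fresh, group labels are
  arbitrary; an optional centroid-correlation alignment against the
  discovery groups is reported, not silently applied.
* **SAM**: `d_i = r_i/(s_i + s0)` with the signed mean difference and
  pooled SE at k = 2 and the standard multiclass contrast
  `r_i = sqrt((n/Π n_g)·Σ_g n_g (x̄_ig − x̄_i)²)`,
  `s_i = sqrt(pooled_var_i · Σ_g 1/n_g)` otherwise (reducing to the
  two-sample t at k = 2). `s0` minimizes the coefficient of variation
  of the windowed MAD of d across the s distribution (the original
  exchangeability rule; a fixed value or median-of-s fallback exists).
  The null comes from label permutations; FDR(δ) = median permuted
  count of |d| ≥ δ over observed calls, and the working δ is the
  smallest with FDR at or below the target.
* **Survival**: product-limit Kaplan-Meier; standard log-rank with
  pooled risk sets, per-group O/E and the hypergeometric covariance
  (quadratic form on k−1 components for k groups); hazard ratio by
  Mantel-Haenszel `HR = (O₁/E₁)/(O₂/E₂)` with a log-scale CI from
  `1/E₁ + 1/E₂` — matching the graphical-statistics convention rather
  than a Cox fit. A group with zero observed or expected events makes
  the ratio unbounded and is reported as such. Time units are whatever
  the input table uses; nothing converts them.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in minutes on one CPU: layer recovery at 2000 × 300
(the reference conditions above), the network learner exercised at up
to 400 genes with 120 forward steps in the analysis drivers, SAM at
500 genes × 40 samples with 200 permutations, survival at 400 per
group. Convergence: sparse k-means stops at relative objective change
< 1e-6 or 50 iterations; bisection runs 80 halvings; correlations are
clipped to 1 − 1e-15 before logs; all tie-breaks are lexicographic so
every stage is deterministic given its seed; the pipeline fans one
global seed out to stages by fixed offsets and writes a SHA-256
manifest so identical configurations yield identical artifacts.

## Known limitations

* Layer recovery is demonstrated for well-separated planted blocks;
  overlapping biological programs (genes informative for two factors)
  violate the disjoint-block model by construction.
* The PAC rule inherits consensus clustering's blindness to nested
  structure: a stable coarse split of a genuinely hierarchical
  population can mask finer stable splits.
* The Mantel-Haenszel HR is biased toward the null for large effects
  and heavy event fractions; the CI is approximate.
* The forward search is greedy; it reaches a local BIC minimum of the
  decomposable family, not the global one.
* With `n_permutations` small (default 4 in tuning) the gap statistic
  is noisy on weak-signal data; the extraction loop compensates by
  treating low-confidence consensus rounds as stopping candidates.
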