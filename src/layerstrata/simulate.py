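"""Synthetic cohorts with planted, mutually independent informative layers.

The generator emulates a bulk tumor expression cohort in which several
disjoint blocks of genes each carry the signature of an independent
categorical latent factor (e.g. an immune-infiltration state and a
molecular differentiation state), embedded in a large background of
uninformative genes. Optionally, right-censored survival times are
linked to exactly one of the latent factors, so that only that layer
is prognostic.

Scales are log2 expression units. Baseline per-gene means are drawn
from N(8, 2^2), the typical range of log2 FPKM in tumor RNA-seq; group
offsets are equally spaced and centred at zero so that a gene's
overall mean does not depend on group proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

BASELINE_MEAN = 8.0
BASELINE_SD = 2.0


@dataclass(frozen=True)
class LayerSpec:
    """One planted informative layer.

    name : layer label; also prefixes its gene symbols.
    n_genes : number of informative genes in the block.
    k : number of latent groups (>= 2).
    proportions : per-group sample fractions, summing to 1.
    effect : total spread of the group mean offsets, log2 units; the
        extreme groups sit at +/- effect / 2.
    within_sd : residual SD around the group mean, log2 units.
    """

    name: str
    n_genes: int
    k: int
    proportions: tuple
    effect: float
    within_sd: float

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        props = np.asarray(self.proportions, dtype=float)
        if len(props) != self.k:
            raise ValueError("proportions must have length k")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")

    @property
    def offsets(self) -> np.ndarray:
        """Equally spaced group offsets centred at zero."""
        return np.linspace(-self.effect / 2.0, self.effect / 2.0, self.k)

    def gene_names(self) -> list[str]:
        return [f"{self.name}_g{i:04d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class SurvivalLinkSpec:
    """Exponential survival driven by one layer's latent factor.

    driving_layer : name of the LayerSpec whose groups modulate hazard.
    baseline_hazard : events per unit time in group 1.
    hr_per_group : multiplicative hazard per group (first entry 1).
    censor_time : administrative censoring horizon.
    """

    driving_layer: str
    baseline_hazard: float
    hr_per_group: tuple
    censor_time: float

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if any(h <= 0 for h in self.hr_per_group):
            raise ValueError("hr_per_group entries must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")


@dataclass
class SyntheticDataset:
    """Generated cohort plus the planted ground truth."""

    expression: ExpressionMatrix
    truth_labels: pd.DataFrame          # samples x layers, int group in 0..k-1
    truth_gene_sets: dict               # layer name -> list of gene symbols
    survival: pd.DataFrame | None       # columns: sample, time, event
    seed: int

    def __post_init__(self) -> None:
        sets = list(self.truth_gene_sets.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if set(sets[i]) & set(sets[j]):
                    raise ValueError("truth gene sets must be pairwise disjoint")
        genes = set(self.expression.genes)
        for name, gs in self.truth_gene_sets.items():
            if not set(gs) <= genes:
                raise ValueError(f"truth gene set {name!r} not a subset of matrix genes")


def generate_dataset(layer_specs, n_samples: int, n_noise_genes: int,
                     survival: SurvivalLinkSpec | None = None,
                     missing_rate: float = 0.0, seed: int = 0) -> SyntheticDataset:
    """Draw a cohort with the given planted layers.

    Informative gene i of layer L has mean mu_i + offset(z_L(sample))
    and SD within_sd; noise genes have group-independent means; layer
    factors are drawn independently per sample. Missingness is
    completely at random at ``missing_rate``. Identical seed and specs
    give bit-identical output.
    """
    layer_specs = list(layer_specs)
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    names = [sp.name for sp in layer_specs]
    if len(set(names)) != len(names):
        raise ValueError("layer names (hence gene blocks) must be distinct")
    total_genes = sum(sp.n_genes for sp in layer_specs) + n_noise_genes
    if total_genes < 1:
        raise ValueError("need at least one gene")

    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]

    # latent factors, independent across layers
    labels = {}
    for sp in layer_specs:
        labels[sp.name] = rng.choice(sp.k, size=n_samples, p=np.asarray(sp.proportions))
    truth_labels = pd.DataFrame(labels, index=samples)

    blocks = []
    gene_sets = {}
    for sp in layer_specs:
        genes = sp.gene_names()
        gene_sets[sp.name] = genes
        mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=sp.n_genes)
        offs = sp.offsets[labels[sp.name]]                      # per sample
        block = mu[:, None] + offs[None, :] + rng.normal(
            0.0, sp.within_sd, size=(sp.n_genes, n_samples))
        blocks.append(pd.DataFrame(block, index=genes, columns=samples))

    if n_noise_genes > 0:
        noise_genes = [f"noise_g{i:04d}" for i in range(n_noise_genes)]
        mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_noise_genes)
        noise_sd = np.median([sp.within_sd for sp in layer_specs]) if layer_specs else 1.0
        block = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_noise_genes, n_samples))
        blocks.append(pd.DataFrame(block, index=noise_genes, columns=samples))

    values = pd.concat(blocks, axis=0)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        arr = values.to_numpy()
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    surv_table = None
    if survival is not None:
        if survival.driving_layer not in truth_labels.columns:
            raise ValueError(f"driving layer {survival.driving_layer!r} not among layers")
        z = truth_labels[survival.driving_layer].to_numpy()
        hr = np.asarray(survival.hr_per_group, dtype=float)
        if len(hr) != int(truth_labels[survival.driving_layer].max()) + 1 and \
                len(hr) != next(sp.k for sp in layer_specs
                                if sp.name == survival.driving_layer):
            raise ValueError("hr_per_group length must equal the driving layer's k")
        rate = survival.baseline_hazard * hr[z]
        draws = rng.exponential(1.0 / rate)
        time = np.minimum(draws, survival.censor_time)
        event = (draws <= survival.censor_time).astype(int)
        surv_table = pd.DataFrame({"sample": samples, "time": time, "event": event,
                                   "group": z})

    return SyntheticDataset(
        expression=ExpressionMatrix(values),
        truth_labels=truth_labels,
        truth_gene_sets=gene_sets,
        survival=surv_table,
        seed=seed,
    )


def count_mode(dataset: SyntheticDataset, library_size: int = 1_000_000,
               zero_inflation: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Turn the log2 matrix into a count table, RNA-seq style.

    Per sample, each gene's expected count is ``library_size`` times
    its relative linear-scale abundance; counts are Poisson draws, and
    excess zeroes are injected completely at random at rate
    ``zero_inflation``. Missing log2 cells count as zero abundance.
    """
    if not (0 <= zero_inflation < 1):
        raise ValueError("zero_inflation must be in [0, 1)")
    if library_size < 0:
        raise ValueError("library_size must be >= 0")
    rng = np.random.default_rng(seed)
    log2 = dataset.expression.values.to_numpy()
    linear = np.where(np.isnan(log2), 0.0, np.exp2(np.where(np.isnan(log2), 0.0, log2)))
    colsum = linear.sum(axis=0)
    colsum[colsum == 0] = 1.0
    expected = library_size * linear / colsum
    counts = rng.poisson(expected).astype(np.int64)
    if zero_inflation > 0:
        dropout = rng.random(counts.shape) < zero_inflation
        counts[dropout] = 0
    return pd.DataFrame(counts, index=dataset.expression.genes,
                        columns=dataset.expression.samples)
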