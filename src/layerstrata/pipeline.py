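"""End-to-end orchestration: simulate -> preprocess -> network ->
activities -> layer extraction -> merge -> SAM -> survival.

One global seed governs a run; stage seeds are derived by fixed
offsets. Every intermediate is written as plain text under the output
directory, the configuration is mirrored verbatim, and a manifest
records the SHA-256 of every artifact so that two runs with the same
config and seed can be compared checksum-by-checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .activity import activity_comparison_report, compute_node_activity
from .consensus import consensus_cluster
from .enrich import WITHOUT_FUNCTION, annotate_branches
from .expression import ExpressionMatrix
from .layers import extract_layers, merge_layers
from .network import forward_bic_search, max_likelihood_tree, split_branches
from .preprocess import PreprocessConfig, preprocess_tcga
from .samstat import sam
from .simulate import LayerSpec, SurvivalLinkSpec, generate_dataset
from .survival import hazard_ratio, logrank_test

# seed offsets per stage (single-knob reproducibility)
_OFF_SIMULATE = 11
_OFF_PREPROCESS = 23
_OFF_LAYERS = 37
_OFF_MERGE = 41
_OFF_SAM = 53
_OFF_TRANSFER = 67


def default_config() -> dict:
    """A small, self-contained discovery run on synthetic data."""
    return {
        "seed": 0,
        "output_dir": "results/run",
        "cohort_mode": "discovery",
        "simulate": {
            "n_samples": 150,
            "n_noise_genes": 460,
            "missing_rate": 0.02,
            "layers": [
                {"name": "immune", "n_genes": 60, "k": 2,
                 "proportions": [0.5, 0.5], "effect": 2.0, "within_sd": 1.0},
                {"name": "molecular", "n_genes": 80, "k": 3,
                 "proportions": [0.4, 0.35, 0.25], "effect": 2.0, "within_sd": 1.0},
            ],
            "survival": {"driving_layer": "immune", "baseline_hazard": 0.05,
                         "hr_per_group": [1.0, 4.0], "censor_time": 60.0},
        },
        "preprocess": {"valid_fraction": 0.75, "top_n": 300,
                       "impute_width": 0.3, "impute_downshift": 1.8},
        "network": {"max_added_edges": 40, "target_branches": 4},
        "layers": {"k_range": [2, 6], "max_layers": 6, "resamples": 100,
                   "sample_fraction": 0.8},
        "sam": {"n_permutations": 200, "fdr_target": 0.05},
    }


def validate_config(config: dict) -> list[str]:
    """Statically checkable precondition violations; empty list = valid."""
    violations = []
    if not isinstance(config.get("seed"), int):
        violations.append("seed: must be an integer")
    mode = config.get("cohort_mode", "discovery")
    if mode not in ("discovery", "transfer"):
        violations.append("cohort_mode: must be 'discovery' or 'transfer'")
    if not config.get("output_dir"):
        violations.append("output_dir: required")

    pp = config.get("preprocess", {})
    vf = pp.get("valid_fraction", 0.75)
    if not (0 < vf <= 1):
        violations.append("preprocess.valid_fraction: must be in (0, 1]")
    if pp.get("top_n", 2000) < 2:
        violations.append("preprocess.top_n: must be >= 2")

    sim = config.get("simulate")
    inp = config.get("input", {})
    if mode == "discovery" and sim is None and "expression" not in inp:
        violations.append("simulate or input.expression: one is required")
    if sim is not None:
        for spec in sim.get("layers", []):
            props = spec.get("proportions", [])
            if abs(sum(props) - 1.0) > 1e-9:
                violations.append(f"simulate.layers[{spec.get('name')}].proportions: must sum to 1")
            if spec.get("k", 2) < 2:
                violations.append(f"simulate.layers[{spec.get('name')}].k: must be >= 2")

    if mode == "transfer":
        if "expression" not in inp:
            violations.append("input.expression: required in transfer mode")
        if "layers_gmt" not in inp:
            violations.append("input.layers_gmt: required in transfer mode")
    if config.get("survival_analysis", True) and mode == "transfer" \
            and "survival" not in inp:
        violations.append("input.survival: required for a survival-enabled transfer run")

    kr = config.get("layers", {}).get("k_range", [2, 6])
    if len(kr) != 2 or kr[0] < 2 or kr[1] < kr[0]:
        violations.append("layers.k_range: must be [low >= 2, high >= low]")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_discovery(config: dict) -> dict:
    """Execute the discovery workflow; returns the manifest dict.

    Stage failure aborts with the stage name; artifacts written before
    the failure are preserved in the output directory.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    lio.dump_config(config, out / "config.yaml")
    artifacts = []
    stage = "setup"

    try:
        # -- simulate / load ------------------------------------------
        stage = "simulate"
        annotation = {}
        survival_table = None
        if "simulate" in config and config["simulate"] is not None:
            sim = config["simulate"]
            specs = [LayerSpec(name=s["name"], n_genes=s["n_genes"], k=s["k"],
                               proportions=tuple(s["proportions"]),
                               effect=s["effect"], within_sd=s["within_sd"])
                     for s in sim["layers"]]
            link = None
            if sim.get("survival"):
                sv = sim["survival"]
                link = SurvivalLinkSpec(driving_layer=sv["driving_layer"],
                                        baseline_hazard=sv["baseline_hazard"],
                                        hr_per_group=tuple(sv["hr_per_group"]),
                                        censor_time=sv["censor_time"])
            dataset = generate_dataset(specs, sim["n_samples"], sim["n_noise_genes"],
                                       survival=link,
                                       missing_rate=sim.get("missing_rate", 0.0),
                                       seed=seed + _OFF_SIMULATE)
            raw = dataset.expression
            annotation = {f"{name}_signature": genes
                          for name, genes in dataset.truth_gene_sets.items()}
            survival_table = dataset.survival
            lio.write_expression_tsv(raw, out / "01_expression.tsv")
            _write_table(dataset.truth_labels, out / "01_truth_labels.tsv",
                         index_label="sample")
            lio.write_gmt(dataset.truth_gene_sets, out / "01_truth_gene_sets.gmt")
            if survival_table is not None:
                lio.write_survival_tsv(survival_table, out / "01_survival.tsv")
                artifacts.append(out / "01_survival.tsv")
            artifacts += [out / "01_expression.tsv", out / "01_truth_labels.tsv",
                          out / "01_truth_gene_sets.gmt"]
        else:
            raw = lio.read_expression_tsv(config["input"]["expression"])
            if "survival" in config.get("input", {}):
                survival_table = lio.read_survival_tsv(config["input"]["survival"])
            if "annotation_gmt" in config.get("input", {}):
                annotation = lio.read_gmt(config["input"]["annotation_gmt"])

        # -- preprocess -----------------------------------------------
        stage = "preprocess"
        pp = config.get("preprocess", {})
        pconf = PreprocessConfig(
            valid_fraction=pp.get("valid_fraction", 0.75),
            top_n=pp.get("top_n", 2000),
            impute_width=pp.get("impute_width", 0.3),
            impute_downshift=pp.get("impute_downshift", 1.8),
            seed=seed + _OFF_PREPROCESS,
        )
        matrix = preprocess_tcga(raw, pconf)
        lio.write_expression_tsv(matrix, out / "02_preprocessed.tsv")
        artifacts.append(out / "02_preprocessed.tsv")

        # -- network --------------------------------------------------
        stage = "network"
        net_conf = config.get("network", {})
        tree = max_likelihood_tree(matrix)
        graph = forward_bic_search(tree, matrix,
                                   max_added_edges=net_conf.get("max_added_edges", 40))
        lio.write_graph(graph.graph, out / "03_network_edges.tsv")
        lio.write_graph(graph.graph, out / "03_network.graphml")
        branches = split_branches(graph, net_conf.get("target_branches", 4))
        nodes = annotate_branches(branches, annotation, matrix.genes)
        lio.write_gmt({n.name: n.genes for n in nodes}, out / "03_branches.gmt")
        enrich_rows = [(n.name, len(n.genes), n.main_function, len(n.annotated_genes))
                       for n in nodes]
        _write_table(pd.DataFrame(enrich_rows,
                                  columns=["branch", "n_genes", "main_function",
                                           "n_annotated"]),
                     out / "03_branch_functions.tsv", index=False)
        artifacts += [out / "03_network_edges.tsv", out / "03_network.graphml",
                      out / "03_branches.gmt", out / "03_branch_functions.tsv"]

        # -- node activities ------------------------------------------
        stage = "activity"
        labelled = [n for n in nodes if n.main_function != WITHOUT_FUNCTION]
        activity = None
        if labelled:
            activity = compute_node_activity(matrix, labelled)
            _write_table(activity, out / "04_node_activity.tsv", index_label="node")
            artifacts.append(out / "04_node_activity.tsv")

        # -- layer extraction -----------------------------------------
        stage = "layers"
        lconf = config.get("layers", {})
        kr = lconf.get("k_range", [2, 6])
        layers = extract_layers(matrix, k_range=range(kr[0], kr[1] + 1),
                                max_layers=lconf.get("max_layers", 6),
                                annotation=annotation,
                                seed=seed + _OFF_LAYERS,
                                resamples=lconf.get("resamples", 100),
                                sample_fraction=lconf.get("sample_fraction", 0.8))
        lio.write_gmt({f"layer{ly.index}": ly.genes for ly in layers},
                      out / "05_layers.gmt")
        weights = pd.concat([pd.DataFrame({"layer": ly.index, "gene": ly.genes,
                                           "weight": ly.weights.to_numpy()})
                             for ly in layers]) if layers else \
            pd.DataFrame(columns=["layer", "gene", "weight"])
        _write_table(weights, out / "05_layer_weights.tsv", index=False)
        classif = pd.DataFrame({f"layer{ly.index}": ly.labels for ly in layers}) \
            if layers else pd.DataFrame(index=matrix.samples)
        _write_table(classif, out / "05_layer_labels.tsv", index_label="sample")
        summary = pd.DataFrame(
            [(ly.index, ly.main_function, ly.k, len(ly.genes), ly.redundant_with)
             for ly in layers],
            columns=["layer", "main_function", "k", "n_genes", "redundant_with"])
        _write_table(summary, out / "05_layer_summary.tsv", index=False)
        artifacts += [out / "05_layers.gmt", out / "05_layer_weights.tsv",
                      out / "05_layer_labels.tsv", out / "05_layer_summary.tsv"]

        # per-node activity comparison across the first layer's groups
        if layers and activity is not None:
            report = activity_comparison_report(
                activity, layers[0].labels.loc[activity.columns].to_numpy())
            _write_table(report, out / "04_activity_comparison.tsv", index=False)
            artifacts.append(out / "04_activity_comparison.tsv")

        # -- merge + SAM ----------------------------------------------
        stage = "merge"
        informative = [ly for ly in layers
                       if ly.main_function != WITHOUT_FUNCTION
                       and ly.redundant_with is None]
        merged = None
        if len(informative) >= 2:
            merged = merge_layers(informative, matrix,
                                  k_range=range(kr[0], kr[1] + 1),
                                  seed=seed + _OFF_MERGE,
                                  resamples=lconf.get("resamples", 100),
                                  sample_fraction=lconf.get("sample_fraction", 0.8))
            lio.write_labels_tsv(merged.labels, out / "06_merged_labels.tsv",
                                 layer="merged")
            artifacts.append(out / "06_merged_labels.tsv")

        stage = "sam"
        sconf = config.get("sam", {})
        sam_target = merged if merged is not None else (
            layers[0].classification if layers else None)
        if sam_target is not None:
            union = sorted(set(g for ly in informative for g in ly.genes)) \
                if merged is not None else layers[0].genes
            res = sam(matrix.subset_genes(union),
                      sam_target.labels.loc[matrix.samples].to_numpy(),
                      n_permutations=sconf.get("n_permutations", 200),
                      fdr_target=sconf.get("fdr_target", 0.05),
                      seed=seed + _OFF_SAM)
            report = pd.DataFrame({"gene": res.d.index, "d": res.d.to_numpy(),
                                   "r": res.r.to_numpy(), "s": res.s.to_numpy(),
                                   "significant": [g in set(res.significant_genes)
                                                   for g in res.d.index]})
            _write_table(report, out / "07_sam.tsv", index=False)
            artifacts.append(out / "07_sam.tsv")

        # -- survival -------------------------------------------------
        stage = "survival"
        if survival_table is not None and layers:
            rows = []
            for ly in layers:
                merged_records = survival_table.copy()
                merged_records["group"] = ly.labels.loc[merged_records["sample"]].to_numpy()
                parts = [sub for _, sub in merged_records.groupby("group", sort=True)]
                if len(parts) < 2 or merged_records["event"].sum() == 0:
                    continue
                lr = logrank_test(parts)
                hr = hazard_ratio(parts[0], parts[1]).hr if len(parts) == 2 else np.nan
                rows.append((f"layer{ly.index}", ly.k, lr.chi2, lr.p, hr))
            _write_table(pd.DataFrame(rows, columns=["layer", "k", "chi2", "p", "hr"]),
                         out / "08_survival.tsv", index=False)
            artifacts.append(out / "08_survival.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": seed,
        "cohort_mode": config.get("cohort_mode", "discovery"),
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_transfer(config: dict) -> dict:
    """Transfer mode: re-classify a new cohort on stored layer gene sets."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    lio.dump_config(config, out / "config.yaml")
    artifacts = []

    raw = lio.read_expression_tsv(config["input"]["expression"])
    pp = config.get("preprocess", {})
    pconf = PreprocessConfig(valid_fraction=pp.get("valid_fraction", 0.75),
                             top_n=pp.get("top_n", 2000),
                             seed=seed + _OFF_PREPROCESS)
    matrix = preprocess_tcga(raw, pconf)
    layer_sets = lio.read_gmt(config["input"]["layers_gmt"])
    kr = config.get("layers", {}).get("k_range", [2, 6])

    survival_table = None
    if "survival" in config.get("input", {}):
        survival_table = lio.read_survival_tsv(config["input"]["survival"])

    rows = []
    for i, (name, genes) in enumerate(sorted(layer_sets.items())):
        present = sorted(set(genes) & set(matrix.genes))
        if len(present) < 5:
            rows.append((name, len(genes), len(present), np.nan))
            continue
        cc = consensus_cluster(matrix, present, k_range=range(kr[0], kr[1] + 1),
                               seed=seed + _OFF_TRANSFER + i)
        lio.write_labels_tsv(cc.labels, out / f"transfer_{name}_labels.tsv", layer=name)
        artifacts.append(out / f"transfer_{name}_labels.tsv")
        rows.append((name, len(genes), len(present), cc.chosen_k))
        if survival_table is not None:
            recs = survival_table.copy()
            recs["group"] = cc.labels.loc[recs["sample"]].to_numpy()
            parts = [sub for _, sub in recs.groupby("group", sort=True)]
            if len(parts) >= 2 and recs["event"].sum() > 0:
                lr = logrank_test(parts)
                hr = hazard_ratio(parts[0], parts[1]).hr if len(parts) == 2 else np.nan
                _write_table(pd.DataFrame([(name, cc.chosen_k, lr.chi2, lr.p, hr)],
                                          columns=["layer", "k", "chi2", "p", "hr"]),
                             out / f"transfer_{name}_survival.tsv", index=False)
                artifacts.append(out / f"transfer_{name}_survival.tsv")
    _write_table(pd.DataFrame(rows, columns=["layer", "n_genes", "n_present", "k_new"]),
                 out / "transfer_summary.tsv", index=False)
    artifacts.append(out / "transfer_summary.tsv")

    manifest = {"seed": seed, "cohort_mode": "transfer",
                "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run(config: dict) -> dict:
    """Dispatch on cohort_mode."""
    mode = config.get("cohort_mode", "discovery")
    if mode == "discovery":
        return run_discovery(config)
    return run_transfer(config)
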