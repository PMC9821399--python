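"""Plain-text I/O: expression TSV, GMT gene sets, survival tables, GraphML."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .expression import ExpressionMatrix


def read_expression_tsv(path) -> ExpressionMatrix:
    """Genes as rows (first column = symbol), header = sample IDs."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = None
    return ExpressionMatrix(table)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "layerstrata") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def read_survival_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    return df


def write_survival_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_labels_tsv(labels: pd.Series, path, layer: str = "layer") -> None:
    out = pd.DataFrame({"sample": labels.index, "layer": layer,
                        "cluster": labels.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


def write_graph(graph: nx.Graph, path) -> None:
    """Edge-list TSV (.tsv) or GraphML (.graphml) by extension."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path)
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"{u}\t{v}\n")


def read_allow_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
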