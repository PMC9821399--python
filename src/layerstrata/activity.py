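"""Functional-node activities and their group comparisons.

A node's activity in a sample is the arithmetic mean of the log2
expression of the node's genes annotated with its main function; group
differences in activity are assessed with the Mann-Whitney U test (two
groups) or the Kruskal-Wallis test (more than two groups).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import FunctionalNode
from .expression import ExpressionMatrix

EXACT_MW_MAX_N = 12


def compute_node_activity(matrix: ExpressionMatrix, nodes,
                          use_all_genes: bool = False) -> pd.DataFrame:
    """Per-node, per-sample mean log2 expression (nodes x samples).

    By default only the node's main-function-annotated genes are
    averaged; ``use_all_genes`` switches to the full branch membership.
    """
    if not matrix.is_complete():
        raise ValueError("activity requires a complete matrix")
    rows = {}
    for node in nodes:
        genes = list(node.genes) if use_all_genes else list(node.annotated_genes)
        if not genes:
            raise ValueError(f"node {node.name!r} has no annotated genes")
        missing = set(genes) - set(matrix.genes)
        if missing:
            raise ValueError(f"node {node.name!r}: genes absent from matrix: {sorted(missing)[:5]}")
        rows[node.name] = matrix.values.loc[genes].mean(axis=0)
    return pd.DataFrame(rows).T


def compare_two_groups(activity: pd.Series | np.ndarray, labels) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p for a binary grouping.

    Exact enumeration when the combined n is small (and tie-free),
    normal approximation with tie correction otherwise.
    """
    values = np.asarray(activity, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("compare_two_groups needs exactly 2 group levels")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    small = len(values) <= EXACT_MW_MAX_N and len(np.unique(values)) == len(values)
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_multi_groups(activity: pd.Series | np.ndarray, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (df = k - 1)."""
    values = np.asarray(activity, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def activity_comparison_report(activity: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-node test report (node, test, statistic, p) for a grouping."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    rows = []
    for node in activity.index:
        row = activity.loc[node]
        if k == 2:
            stat, p = compare_two_groups(row, labels)
            test = "mann-whitney"
        else:
            stat, p = compare_multi_groups(row, labels)
            test = "kruskal-wallis"
        rows.append((node, test, stat, p))
    return pd.DataFrame(rows, columns=["node", "test", "statistic", "p"])
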