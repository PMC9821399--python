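"""Decomposable Gaussian graphical model over genes.

The model is learned in two sequential steps: first the maximum
likelihood spanning tree over the genes (Chow-Liu tree with Gaussian
mutual information edge weights), then a greedy forward search that
adds the edge with the most negative BIC change at every step, among
edges whose addition keeps the graph chordal (decomposable). The
chordal graph admits a junction tree, and the Gaussian likelihood
factorizes over its maximal cliques and separators, which is what
makes both the model likelihood and the per-edge BIC change cheap to
evaluate.

For an admissible edge (u, v) with minimal separator S the BIC change
is ``n * ln(1 - r_{uv.S}^2) + ln(n)`` where r_{uv.S} is the partial
correlation of u and v given S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix


# ---------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------

@dataclass
class DecomposableGraph:
    """Chordal gene network with its clique factorization."""

    graph: nx.Graph
    cliques: list = field(default_factory=list)      # list[frozenset]
    separators: list = field(default_factory=list)   # list[frozenset], multiset

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "DecomposableGraph":
        if not nx.is_chordal(graph):
            raise ValueError("graph is not chordal (decomposable)")
        cliques, separators = junction_structure(graph)
        return cls(graph=graph, cliques=cliques, separators=separators)

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def copy(self) -> "DecomposableGraph":
        return DecomposableGraph(self.graph.copy(), list(self.cliques), list(self.separators))


def is_decomposable(graph: nx.Graph) -> bool:
    """True iff the graph is chordal (has a perfect elimination ordering)."""
    return nx.is_chordal(graph)


def junction_structure(graph: nx.Graph):
    """Maximal cliques and junction-tree separator multiset of a chordal graph.

    The junction tree is the maximum-weight spanning tree of the clique
    graph with intersection-size weights; ties are broken on the sorted
    clique labels for determinism. Empty separators (between connected
    components) are dropped — they contribute nothing to the likelihood.
    """
    cliques = sorted(nx.chordal_graph_cliques(graph), key=lambda c: sorted(c))
    if len(cliques) <= 1:
        return list(cliques), []
    # Kruskal on -|intersection| with deterministic tie-break
    edges = []
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            w = len(cliques[i] & cliques[j])
            if w > 0:
                edges.append((-w, i, j))
    edges.sort()
    parent = list(range(len(cliques)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    separators = []
    for negw, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            separators.append(cliques[i] & cliques[j])
    return list(cliques), separators


# ---------------------------------------------------------------------
# Gaussian building blocks
# ---------------------------------------------------------------------

def gaussian_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI of two jointly Gaussian variables from their sample correlation.

    MI = -0.5 * ln(1 - r^2), in nats; 0 iff the sample correlation is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1.0 - 1e-15)
    return -0.5 * math.log1p(-r2)


def _correlation_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    X = matrix.to_array()
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [matrix.genes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance genes: {bad[:5]}")
    return np.corrcoef(X)


def max_likelihood_tree(matrix: ExpressionMatrix) -> DecomposableGraph:
    """Maximum-likelihood spanning tree (Chow-Liu with Gaussian MI weights).

    Deterministic: ties broken lexicographically on the gene pair.
    """
    genes = matrix.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    corr = _correlation_matrix(matrix)
    r2 = np.clip(corr ** 2, 0.0, 1.0 - 1e-15)
    mi = -0.5 * np.log1p(-r2)
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            edges.append((-mi[i, j], genes[i], genes[j]))
    edges.sort()

    parent = {g: g for g in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    tree = nx.Graph()
    tree.add_nodes_from(genes)
    for negmi, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add_edge(u, v)
        if tree.number_of_edges() == len(genes) - 1:
            break
    return DecomposableGraph.from_graph(tree)


# ---------------------------------------------------------------------
# likelihood and BIC
# ---------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


def _marginal_loglik(cov: np.ndarray, idx: list, n: int) -> float:
    """Max log-likelihood of the saturated Gaussian on variables ``idx``.

    ``cov`` is the MLE covariance (denominator n) of the full gene set.
    """
    if not idx:
        return 0.0
    sub = cov[np.ix_(idx, idx)]
    sign, logdet = np.linalg.slogdet(sub)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance block")
    p = len(idx)
    return -0.5 * n * (p * _LOG_2PI + logdet + p)


def model_loglik(graph: DecomposableGraph, matrix: ExpressionMatrix) -> float:
    """Gaussian log-likelihood by clique/separator factorization."""
    X = matrix.to_array()
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    n = matrix.n_samples
    cov = np.cov(X, ddof=0)
    cov = np.atleast_2d(cov)
    pos = {g: i for i, g in enumerate(matrix.genes)}
    missing = set(graph.graph.nodes) - set(pos)
    if missing:
        raise ValueError(f"graph nodes absent from matrix: {sorted(missing)[:5]}")
    ll = 0.0
    for clique in graph.cliques:
        idx = sorted(pos[g] for g in clique)
        try:
            ll += _marginal_loglik(cov, idx, n)
        except np.linalg.LinAlgError:
            raise ValueError(f"singular covariance for clique {sorted(clique)}")
    for sep in graph.separators:
        idx = sorted(pos[g] for g in sep)
        ll -= _marginal_loglik(cov, idx, n)
    return ll


def model_bic(graph: DecomposableGraph, matrix: ExpressionMatrix) -> float:
    """BIC = -2 loglik + df ln(n), df = 2 * n_nodes + n_edges."""
    n = matrix.n_samples
    df = 2 * graph.graph.number_of_nodes() + graph.graph.number_of_edges()
    return -2.0 * model_loglik(graph, matrix) + df * math.log(n)


# ---------------------------------------------------------------------
# forward search
# ---------------------------------------------------------------------

@dataclass
class EdgeCandidate:
    """A decomposability-preserving edge addition and its BIC change."""

    u: str
    v: str
    separator: frozenset
    partial_correlation: float
    delta_bic: float


def _partial_correlation(cov: np.ndarray, iu: int, iv: int, isep: list) -> float:
    idx = [iu, iv] + list(isep)
    sub = cov[np.ix_(idx, idx)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


def _junction_tree_adjacency(cliques):
    """Max-weight junction tree over the cliques; adjacency with weights."""
    adj = {i: [] for i in range(len(cliques))}
    edges = []
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            w = len(cliques[i] & cliques[j])
            if w > 0:
                edges.append((-w, i, j))
    edges.sort()
    parent = list(range(len(cliques)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for negw, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            adj[i].append((j, -negw))
            adj[j].append((i, -negw))
    return adj


def legal_edge_additions(graph: nx.Graph):
    """All decomposability-preserving single-edge additions.

    Two maximal cliques Ci, Cj of a chordal graph can be made adjacent
    in some junction tree iff |Ci & Cj| equals the minimum separator
    weight on the junction-tree path between them; for such a pair,
    joining any u in Ci \\ S to any v in Cj \\ S (S = Ci & Cj) keeps
    the graph chordal, creates the unique new clique S | {u, v}, and
    changes the likelihood through the partial correlation r_{uv.S}.
    Yields (u, v, S) triples with u < v, deduplicated.
    """
    cliques = sorted(nx.chordal_graph_cliques(graph), key=lambda c: sorted(c))
    nc = len(cliques)
    if nc <= 1:
        return []
    adj = _junction_tree_adjacency(cliques)

    # minimum separator weight on the junction-tree path between all pairs
    minw = np.zeros((nc, nc), dtype=int)
    for start in range(nc):
        stack = [(start, 10 ** 9)]
        seen = {start}
        while stack:
            node, mw = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    minw[start, nxt] = min(mw, w)
                    stack.append((nxt, min(mw, w)))

    moves = {}
    for i in range(nc):
        for j in range(i + 1, nc):
            sep = cliques[i] & cliques[j]
            # cross-component pairs have minw 0 and empty separator: legal
            if len(sep) != minw[i, j]:
                continue
            for u in cliques[i] - sep:
                for v in cliques[j] - sep:
                    if graph.has_edge(u, v):
                        continue
                    key = (u, v) if u < v else (v, u)
                    if key not in moves:
                        moves[key] = sep
    return [(u, v, moves[(u, v)]) for u, v in sorted(moves)]


def forward_bic_search(tree: DecomposableGraph, matrix: ExpressionMatrix,
                       max_added_edges: int | None = None,
                       return_trace: bool = False):
    """Greedy BIC-minimizing edge addition preserving decomposability.

    At each step the admissible edge with the most negative BIC change
    is added; the search stops when no candidate improves BIC or when
    ``max_added_edges`` is reached. Admissible edges are enumerated
    from the junction tree (see ``legal_edge_additions``), so no
    per-candidate chordality test is needed. Ties are broken
    lexicographically on the gene pair.
    """
    if not nx.is_chordal(tree.graph):
        raise ValueError("input graph is not decomposable")
    X = matrix.to_array()
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    n = matrix.n_samples
    cov = np.atleast_2d(np.cov(X, ddof=0))
    pos = {g: i for i, g in enumerate(matrix.genes)}

    graph = tree.graph.copy()
    trace = []
    added = 0
    log_n = math.log(n)
    while max_added_edges is None or added < max_added_edges:
        best = None
        for u, v, sep in legal_edge_additions(graph):
            isep = sorted(pos[g] for g in sep)
            r = _partial_correlation(cov, pos[u], pos[v], isep)
            r2 = min(r * r, 1.0 - 1e-15)
            delta = n * math.log1p(-r2) + log_n
            if delta >= 0:
                continue
            key = (delta, u, v)
            if best is None or key < (best.delta_bic, best.u, best.v):
                best = EdgeCandidate(u=u, v=v, separator=sep,
                                     partial_correlation=r, delta_bic=delta)
        if best is None:
            break
        graph.add_edge(best.u, best.v)
        trace.append(best)
        added += 1
    result = DecomposableGraph.from_graph(graph)
    if return_trace:
        return result, trace
    return result


# ---------------------------------------------------------------------
# branch splitting
# ---------------------------------------------------------------------

def split_branches(graph: DecomposableGraph | nx.Graph, target_branches: int):
    """Partition the network into connected branches by edge betweenness.

    Iteratively removes the highest-betweenness edge (ties broken on the
    lexicographic edge) until the component count reaches the target.
    Returns the branches as sorted gene lists, largest first.
    """
    g = graph.graph.copy() if isinstance(graph, DecomposableGraph) else graph.copy()
    n_nodes = g.number_of_nodes()
    if not (1 <= target_branches <= n_nodes):
        raise ValueError("target_branches must be between 1 and the node count")
    if nx.number_connected_components(g) > target_branches:
        raise ValueError("graph already has more components than target_branches")
    while nx.number_connected_components(g) < target_branches:
        btw = nx.edge_betweenness_centrality(g)
        # tie-break: highest betweenness, then lexicographically smallest edge
        top = max(btw.values())
        ties = sorted(tuple(sorted(e)) for e, b in btw.items() if b == top)
        g.remove_edge(*ties[0])
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c))
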