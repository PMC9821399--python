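"""Decomposable-GGM learner: MI, tree, chordality, BIC, search, branches."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from layerstrata import (gaussian_mutual_information, is_decomposable,
                         max_likelihood_tree, model_bic, split_branches)
from layerstrata.enrich import (WITHOUT_FUNCTION, enrich_main_function,
                                enrichment_table)
from layerstrata.network import (DecomposableGraph, forward_bic_search,
                                 legal_edge_additions, model_loglik)

from conftest import make_matrix


# ------------------------------------------------------------------ helpers

def correlated_pair(rng, r, n=2000):
    """Two vectors with sample correlation exactly r (Gram-Schmidt)."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    return x, r * x + math.sqrt(1 - r * r) * z


def gaussian_mi_matrix(matrix):
    corr = np.corrcoef(matrix.to_array())
    return -0.5 * np.log1p(-np.clip(corr ** 2, 0, 1 - 1e-15))


def all_spanning_trees(n):
    """Labeled spanning trees on n nodes via Prufer sequences."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        deg = [1] * n
        for s in seq:
            deg[s] += 1
        edges = []
        dd = list(deg)
        leaves = sorted(i for i in range(n) if dd[i] == 1)
        for s in seq:
            leaf = leaves.pop(0)
            edges.append((leaf, s))
            dd[s] -= 1
            if dd[s] == 1:
                import bisect
                bisect.insort(leaves, s)
        edges.append((leaves[0], leaves[1]))
        yield edges


# ------------------------------------------------------------------ MI

class TestMutualInformation:
    def test_closed_form_at_r_06(self, rng):
        x, y = correlated_pair(rng, 0.6)
        assert gaussian_mutual_information(x, y) == pytest.approx(
            -0.5 * math.log(1 - 0.36), abs=1e-10)

    def test_near_identical_is_large(self, rng):
        x = rng.normal(size=500)
        y = x + 1e-3 * rng.normal(size=500)
        assert gaussian_mutual_information(x, y) > 3.0

    def test_independent_is_near_zero(self, rng):
        x, y = rng.normal(size=(2, 10_000))
        assert gaussian_mutual_information(x, y) < 0.001

    def test_symmetry(self, rng):
        x, y = correlated_pair(rng, 0.3, n=100)
        assert gaussian_mutual_information(x, y) == pytest.approx(
            gaussian_mutual_information(y, x))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_mutual_information(np.ones(10), np.arange(10.0))


# ------------------------------------------------------------------ tree

class TestMaxLikelihoodTree:
    def test_three_gene_tree_keeps_strongest_edges(self, rng):
        # r12=0.9, r13=0.8 both through gene 0; brute force picks {0-1, 0-2}
        x0 = rng.normal(size=500)
        x1 = 0.9 * x0 + math.sqrt(1 - 0.81) * rng.normal(size=500)
        x2 = 0.8 * x0 + math.sqrt(1 - 0.64) * rng.normal(size=500)
        m = make_matrix(np.vstack([x0, x1, x2]))
        tree = max_likelihood_tree(m)
        mi = gaussian_mi_matrix(m)
        best = max(all_spanning_trees(3),
                   key=lambda es: sum(mi[a, b] for a, b in es))
        expected = sorted(tuple(sorted((f"g{a:03d}", f"g{b:03d}"))) for a, b in best)
        assert tree.edges == expected

    def test_five_gene_tree_matches_cayley_enumeration(self, rng):
        X = rng.normal(size=(5, 60))
        X[1] += 0.7 * X[0]
        X[3] += 0.5 * X[2]
        m = make_matrix(X)
        tree = max_likelihood_tree(m)
        mi = gaussian_mi_matrix(m)
        genes = m.genes
        gi = {g: i for i, g in enumerate(genes)}
        got = sum(mi[gi[u], gi[v]] for u, v in tree.edges)
        best = max(sum(mi[a, b] for a, b in es) for es in all_spanning_trees(5))
        assert got == pytest.approx(best, abs=1e-12)

    def test_two_genes_single_edge(self, rng):
        m = make_matrix(rng.normal(size=(2, 10)))
        tree = max_likelihood_tree(m)
        assert tree.edges == [("g000", "g001")]

    def test_edge_count_and_connectivity(self, rng):
        m = make_matrix(rng.normal(size=(12, 30)))
        tree = max_likelihood_tree(m)
        assert tree.graph.number_of_edges() == 11
        assert nx.is_connected(tree.graph)


# ------------------------------------------------------------------ chordality

@pytest.mark.parametrize("graph,expected", [
    (nx.path_graph(5), True),
    (nx.cycle_graph(4), False),
    (nx.complete_graph(4), True),
    (nx.random_labeled_tree(10, seed=1), True),
])
def test_is_decomposable(graph, expected):
    assert is_decomposable(graph) is expected


# ------------------------------------------------------------------ likelihood

class TestModelLikelihood:
    def test_empty_graph_is_independence_factorization(self, rng):
        X = rng.normal(size=(4, 60))
        X[1] += X[0]
        m = make_matrix(X)
        g = nx.empty_graph(m.genes)
        ll = model_loglik(DecomposableGraph.from_graph(g), m)
        cov = np.cov(X, ddof=0)
        n = 60
        ll_ind = sum(-0.5 * n * (math.log(2 * math.pi) + math.log(cov[i, i]) + 1)
                     for i in range(4))
        assert ll == pytest.approx(ll_ind, abs=1e-8)

    def test_complete_graph_is_multivariate_normal(self, rng):
        X = rng.normal(size=(4, 60))
        X[2] += 0.5 * X[0]
        m = make_matrix(X)
        g = nx.complete_graph(m.genes)
        ll = model_loglik(DecomposableGraph.from_graph(g), m)
        cov = np.cov(X, ddof=0)
        _, logdet = np.linalg.slogdet(cov)
        ll_mvn = -0.5 * 60 * (4 * math.log(2 * math.pi) + logdet + 4)
        assert ll == pytest.approx(ll_mvn, abs=1e-8)

    def test_adding_edge_never_decreases_loglik(self, rng):
        X = rng.normal(size=(5, 40))
        m = make_matrix(X)
        g = nx.random_labeled_tree(5, seed=3)
        g = nx.relabel_nodes(g, {i: m.genes[i] for i in range(5)})
        ll = model_loglik(DecomposableGraph.from_graph(g), m)
        for u, v, _ in legal_edge_additions(g):
            g2 = g.copy()
            g2.add_edge(u, v)
            ll2 = model_loglik(DecomposableGraph.from_graph(g2), m)
            assert ll2 >= ll - 1e-9


# ------------------------------------------------------------------ forward search

class TestForwardSearch:
    def test_independent_genes_add_no_edges(self, rng):
        m = make_matrix(rng.normal(size=(8, 200)))
        tree = max_likelihood_tree(m)
        out, trace = forward_bic_search(tree, m, return_trace=True)
        assert trace == []
        assert out.edges == tree.edges

    def test_three_clique_chord_is_added(self, rng):
        prec = np.array([[1, -0.4, -0.4], [-0.4, 1, -0.4], [-0.4, -0.4, 1]])
        X = rng.multivariate_normal(np.zeros(3), np.linalg.inv(prec), size=400).T
        m = make_matrix(X)
        tree = max_likelihood_tree(m)
        out = forward_bic_search(tree, m)
        assert out.graph.number_of_edges() == 3
        assert model_bic(out, m) < model_bic(tree, m)

    def test_max_added_edges_zero_is_identity(self, rng):
        m = make_matrix(rng.normal(size=(6, 50)))
        tree = max_likelihood_tree(m)
        out = forward_bic_search(tree, m, max_added_edges=0)
        assert out.edges == tree.edges

    def test_incremental_delta_matches_full_recomputation(self, rng):
        """delta_bic from the junction tree equals the BIC difference."""
        for _ in range(8):
            X = rng.normal(size=(6, 50)) + 0.6 * rng.normal(size=(1, 50))
            m = make_matrix(X)
            tree = max_likelihood_tree(m)
            out, trace = forward_bic_search(tree, m, return_trace=True)
            g = tree.graph.copy()
            bic_prev = model_bic(tree, m)
            for cand in trace:
                g.add_edge(cand.u, cand.v)
                assert nx.is_chordal(g)
                bic_now = model_bic(DecomposableGraph.from_graph(g), m)
                assert bic_now - bic_prev == pytest.approx(cand.delta_bic, abs=1e-8)
                assert bic_now < bic_prev
                bic_prev = bic_now

    def test_legal_moves_match_chordality_brute_force(self, rng):
        """Junction-tree move enumeration equals try-and-check enumeration."""
        for trial in range(20):
            g = nx.random_labeled_tree(int(rng.integers(4, 9)),
                                       seed=int(rng.integers(1_000_000)))
            for _ in range(int(rng.integers(0, 4))):
                mv = legal_edge_additions(g)
                if not mv:
                    break
                u, v, _ = mv[int(rng.integers(len(mv)))]
                g.add_edge(u, v)
            moves = {(u, v) for u, v, _ in legal_edge_additions(g)}
            brute = set()
            for u, v in itertools.combinations(sorted(g.nodes), 2):
                if g.has_edge(u, v):
                    continue
                g.add_edge(u, v)
                if nx.is_chordal(g):
                    brute.add((u, v))
                g.remove_edge(u, v)
            assert moves == brute


# ------------------------------------------------------------------ branches

class TestSplitBranches:
    def test_path_graph_splits_at_middle_edge(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        parts = split_branches(g, 2)
        assert sorted(map(sorted, parts)) == [["a", "b"], ["c", "d"]]

    def test_target_one_returns_all_nodes(self):
        g = nx.path_graph(["a", "b", "c"])
        assert split_branches(g, 1) == [["a", "b", "c"]]

    def test_partition_property(self, rng):
        m = make_matrix(rng.normal(size=(15, 40)))
        tree = max_likelihood_tree(m)
        parts = split_branches(tree, 4)
        assert len(parts) == 4
        union = sorted(g for p in parts for g in p)
        assert union == sorted(m.genes)
        sub = tree.graph
        for p in parts:
            assert nx.is_connected(sub.subgraph(p))

    def test_unreachable_target_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")  # 4 components already
        with pytest.raises(ValueError):
            split_branches(g, 2)


# ------------------------------------------------------------------ enrichment

class TestEnrichment:
    def test_perfect_overlap_hits_hypergeometric_floor(self):
        background = [f"g{i}" for i in range(100)]
        branch = background[:10]
        annotation = {"immune": background[:10]}
        term, p, _ = enrich_main_function(branch, annotation, background)
        assert term == "immune"
        assert p == pytest.approx(1.0 / comb(100, 10, exact=True), rel=1e-9)

    def test_background_frequency_gives_q_near_one(self, rng):
        background = [f"g{i}" for i in range(200)]
        annotation = {"termA": background[::2], "termB": background[1::2]}
        branch = list(rng.choice(background, size=20, replace=False))
        term, p, table = enrich_main_function(branch, annotation, background)
        assert term in annotation
        assert table["q"].min() > 0.05

    def test_no_overlap_is_without_function(self):
        background = [f"g{i}" for i in range(50)]
        annotation = {"immune": background[:10]}
        term, p, _ = enrich_main_function(background[20:30], annotation, background)
        assert term == WITHOUT_FUNCTION and p == 1.0

    def test_empty_annotation_is_without_function(self):
        term, _, _ = enrich_main_function(["g1"], {}, ["g1", "g2"])
        assert term == WITHOUT_FUNCTION

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrichment_table(["x"], {"t": ["a"]}, ["a", "b"])
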