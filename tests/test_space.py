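import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdgspace as s
from sdgspace.errors import DegenerateInputError
from sdgspace.space import COSINE, CONDITIONAL_PRODUCT


def binary(values):
    arr = np.asarray(values, dtype=int)
    return s.BinaryAdvantageMatrix(m=pd.DataFrame(
        arr, index=[f"C{i}" for i in range(arr.shape[0])],
        columns=[f"I{j}" for j in range(arr.shape[1])]))


def prox_of(matrix, labels):
    frame = pd.DataFrame(np.asarray(matrix, dtype=float),
                         index=labels, columns=labels)
    return s.ProximityMatrix(s=frame, formula=COSINE)


class TestProximity:
    def test_identical_columns_are_at_distance_one(self):
        p = s.proximity_matrix(binary([[1, 1], [1, 1], [0, 0]]))
        assert np.allclose(p.s.to_numpy(), 1.0)

    def test_disjoint_columns_are_at_zero(self):
        p = s.proximity_matrix(binary([[1, 0], [0, 1]]))
        assert p.s.iloc[0, 1] == 0.0

    def test_hand_value_cosine_and_conditional_product(self):
        m = binary(np.array([[1, 1], [1, 0], [0, 1], [0, 0]]))
        cos = s.proximity_matrix(m, formula=COSINE)
        cond = s.proximity_matrix(m, formula=CONDITIONAL_PRODUCT)
        assert cos.s.iloc[0, 1] == pytest.approx(0.5)
        assert cond.s.iloc[0, 1] == pytest.approx(0.25)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_conditional_product_is_cosine_squared(self, seed):
        """The product of the two pairwise conditional probabilities is
        the square of the cosine similarity, entrywise."""
        rng = np.random.default_rng(seed)
        mat = (rng.random((rng.integers(3, 10), rng.integers(2, 8))) < 0.5)
        mat = mat.astype(int)
        mat[0, mat.sum(axis=0) == 0] = 1  # full column support
        m = binary(mat)
        cos = s.proximity_matrix(m, formula=COSINE).s.to_numpy()
        cond = s.proximity_matrix(m, formula=CONDITIONAL_PRODUCT).s.to_numpy()
        assert np.abs(cond - cos ** 2).max() < 1e-12
        assert np.allclose(cos, cos.T)
        assert cos.min() >= 0.0 and cos.max() <= 1.0

    def test_zero_ubiquity_directs_to_prune(self):
        with pytest.raises(DegenerateInputError, match="prune"):
            s.proximity_matrix(binary([[1, 0], [1, 0]]))


class TestTradeoff:
    def test_complement_and_involution(self):
        p = s.proximity_matrix(binary([[1, 1], [1, 0], [0, 1], [0, 0]]))
        ts = s.tradeoff_matrix(p)
        assert ts.s.iloc[0, 1] == pytest.approx(0.5)
        assert ts.s.iloc[0, 0] == 0.0  # diagonal: no self trade-off
        back = s.tradeoff_matrix(ts)
        pd.testing.assert_frame_equal(back.s, p.s)

    def test_requires_cosine(self):
        p = s.proximity_matrix(binary([[1, 1], [0, 1]]),
                               formula=CONDITIONAL_PRODUCT)
        with pytest.raises(DegenerateInputError):
            s.tradeoff_matrix(p)


def brute_force_max_spanning_tree(p):
    """Exhaustive oracle: enumerate all spanning trees for n <= 6."""
    labels = list(p.s.index)
    n = len(labels)
    edges = [(a, b, float(p.s.loc[a, b]))
             for a, b in itertools.combinations(labels, 2)
             if p.s.loc[a, b] > 0]
    best, best_w = None, -1.0
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_weighted_edges_from(combo)
        if nx.is_connected(g):
            w = sum(e[2] for e in combo)
            if w > best_w:
                best, best_w = combo, w
    return best, best_w


class TestMaximumSpanningTree:
    def test_three_node_hand_case(self):
        p = prox_of([[1.0, 0.9, 0.5], [0.9, 1.0, 0.4], [0.5, 0.4, 1.0]],
                    ["A", "B", "C"])
        tree = s.maximum_spanning_tree(p)
        assert {(a, b) for a, b, _ in tree} == {("A", "B"), ("A", "C")}
        assert sum(w for _, _, w in tree) == pytest.approx(1.4)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        sym = rng.random((n, n))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 1.0)
        p = prox_of(sym, [f"N{i}" for i in range(n)])
        tree = s.maximum_spanning_tree(p)
        _, best_w = brute_force_max_spanning_tree(p)
        assert sum(w for _, _, w in tree) == pytest.approx(best_w)

    def test_disconnected_raises_with_components(self):
        p = prox_of([[1, 0.5, 0, 0], [0.5, 1, 0, 0],
                     [0, 0, 1, 0.7], [0, 0, 0.7, 1]], list("ABCD"))
        with pytest.raises(DegenerateInputError, match="2 components"):
            s.maximum_spanning_tree(p)
        forest = s.maximum_spanning_tree(p, allow_forest=True)
        assert len(forest) == 2

    def test_96_node_backbone_has_95_edges(self, study_scale_year):
        _, _, m, idx, _ = study_scale_year
        p = s.proximity_matrix(m)
        g = s.build_space_graph(p, node_scores=idx.gsi)
        assert len(p.labels) == 96
        assert len(g.mst_edges) == 95
        mst_only = nx.Graph(
            [(a, b) for a, b in g.mst_edges])
        assert nx.is_connected(mst_only)

    def test_high_threshold_leaves_mst_only(self, study_scale_year):
        _, _, m, idx, _ = study_scale_year
        p = s.proximity_matrix(m)
        g = s.build_space_graph(p, threshold=1.01, node_scores=idx.gsi)
        assert g.graph.number_of_edges() == 95
        assert all(d["in_mst"] for _, _, d in g.graph.edges(data=True))


def modularity_best_two_cut(graph):
    """Exhaustive oracle: best modularity over all 2-partitions."""
    nodes = sorted(graph.nodes)
    best, best_q = None, -np.inf
    for size in range(1, len(nodes) // 2 + 1):
        for left in itertools.combinations(nodes, size):
            part = [set(left), set(nodes) - set(left)]
            q = nx.algorithms.community.modularity(graph, part)
            if q > best_q:
                best, best_q = part, q
    return best


class TestCommunities:
    def test_path_splits_in_the_middle(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        for a, b in g.edges:
            g[a][b].update(weight=1.0, in_mst=True)
        comm = s.detect_communities(s.SpaceGraph(graph=g, threshold=0.7))
        groups = {}
        for node, c in comm.items():
            groups.setdefault(c, set()).add(node)
        assert set(map(frozenset, groups.values())) == \
            {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_bridge_between_cliques_is_cut(self):
        g = nx.Graph()
        left, right = ["A", "B", "C"], ["X", "Y", "Z"]
        g.add_edges_from(itertools.combinations(left, 2))
        g.add_edges_from(itertools.combinations(right, 2))
        g.add_edge("C", "X")
        comm = s.detect_communities(s.SpaceGraph(graph=g, threshold=0.7))
        assert {n for n, c in comm.items() if c == comm["A"]} == set(left)
        oracle = modularity_best_two_cut(g)
        assert set(map(frozenset, oracle)) == {frozenset(left), frozenset(right)}

    def test_already_split_graph_returned_unchanged(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        comm = s.detect_communities(s.SpaceGraph(graph=g, threshold=0.7))
        assert comm["A"] == comm["B"] != comm["C"] == comm["D"]

    def test_k_larger_than_node_count_rejected(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(DegenerateInputError):
            s.detect_communities(s.SpaceGraph(graph=g, threshold=0.7), k=3)

    def test_community_one_has_higher_mean_score(self, study_scale_year):
        _, _, m, idx, _ = study_scale_year
        p = s.proximity_matrix(m)
        g = s.build_space_graph(p, node_scores=idx.gsi)
        comm = g.communities()
        means = {}
        for c in set(comm.values()):
            members = [n for n in comm if comm[n] == c]
            means[c] = idx.gsi[members].mean()
        assert means[1] > means[2]

    def test_threshold_sweep_is_structure_stable(self, study_scale_year):
        """Well-separated data: identical 2-community partition for every
        threshold between 0.5 and 0.9 (pairwise ARI = 1)."""
        _, _, m, idx, _ = study_scale_year
        p = s.proximity_matrix(m)
        report = s.sweep_threshold(p, [0.5, 0.6, 0.7, 0.8, 0.9],
                                   node_scores=idx.gsi)
        assert not report["degenerate"].any()
        assert (report["ari"] == 1.0).all()


class TestLayout:
    def test_deterministic(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        sg1 = s.SpaceGraph(graph=g.copy(), threshold=0.7)
        sg2 = s.SpaceGraph(graph=g.copy(), threshold=0.7)
        assert s.layout_graph(sg1, seed=1) == s.layout_graph(sg2, seed=1)

    def test_two_nodes_distinct(self):
        g = nx.Graph([("A", "B")])
        coords = s.layout_graph(s.SpaceGraph(graph=g, threshold=0.7), seed=0)
        assert coords["A"] != coords["B"]

    def test_planted_blocks_are_spatially_separated(self, clean_year):
        matrix, _, m, truth = clean_year
        idx = s.eigen_indices(m, scores=matrix)
        p = s.proximity_matrix(m)
        g = s.build_space_graph(p, node_scores=idx.gsi, allow_forest=True)
        coords = s.layout_graph(g, seed=0)
        within, cross = [], []
        for a, b in itertools.combinations(coords, 2):
            d = np.hypot(coords[a][0] - coords[b][0],
                         coords[a][1] - coords[b][1])
            same = truth.indicator_block[a] == truth.indicator_block[b]
            (within if same else cross).append(d)
        assert np.mean(within) < np.mean(cross)


class TestCountrySpace:
    def test_transpose_symmetry(self, clean_year):
        _, _, m, _ = clean_year
        cg = s.country_space(m, allow_forest=True)
        transposed = s.BinaryAdvantageMatrix(m=m.m.T)
        p = s.proximity_matrix(transposed)
        direct = s.build_space_graph(p, allow_forest=True)
        assert set(cg.graph.edges) == set(direct.graph.edges)

    def test_planted_country_communities(self, study_scale_year):
        matrix, _, m, idx, truth = study_scale_year
        cg = s.country_space(m, node_scores=idx.csi)
        comm = cg.communities()
        blocks = {c: truth.country_block[c] for c in comm}
        from sklearn.metrics import adjusted_rand_score
        nodes = sorted(comm)
        assert adjusted_rand_score([blocks[n] for n in nodes],
                                   [comm[n] for n in nodes]) == 1.0

    def test_single_country_rejected(self):
        m = s.BinaryAdvantageMatrix(m=pd.DataFrame([[1, 0]], index=["C0"],
                                                   columns=["I0", "I1"]))
        with pytest.raises(DegenerateInputError):
            s.country_space(m)


def test_space_export_round_trip(tmp_path, clean_year):
    matrix, _, m, _ = clean_year
    idx = s.eigen_indices(m, scores=matrix)
    p = s.proximity_matrix(m)
    g = s.build_space_graph(p, node_scores=idx.gsi, allow_forest=True)
    s.layout_graph(g)
    path = s.write_space(g, tmp_path / "space.graphml", fmt="graphml")
    back = nx.read_graphml(path)
    assert set(back.nodes) == set(g.graph.nodes)
    assert back.nodes[sorted(back.nodes)[0]].keys() >= \
        {"score", "degree", "community", "x", "y"}
    s.write_space(g, tmp_path / "space.gexf", fmt="gexf")
    s.write_space(g, tmp_path / "space", fmt="csv")
    assert (tmp_path / "space.edges.csv").exists()
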