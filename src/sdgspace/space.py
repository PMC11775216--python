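"""Relatedness "spaces": proximity matrices and backbone graphs.

The indicator space is built from the binary advantage matrix M: two
indicators are close when the same countries tend to be specialized in
both. The canonical proximity is the cosine similarity of the binary
indicator columns,

    S[i, j] = co(i, j) / sqrt(k_i * k_j),

with ``co`` the number of countries specialized in both and ``k`` the
ubiquities. The product of the two pairwise conditional probabilities,
``co^2 / (k_i k_j)``, equals S squared and is kept as a diagnostic variant.

The rendered graph is the maximum spanning tree of the proximity matrix
(which reaches every node with n-1 edges) overlaid with every edge at or
above a proximity threshold (default 0.7). Two communities are extracted
with the Girvan-Newman procedure: repeatedly delete the edge of highest
(unweighted) betweenness until the graph splits.

The same machinery applied to M transposed yields the country space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .rca import BinaryAdvantageMatrix

DEFAULT_THRESHOLD = 0.7

COSINE = "cosine"
CONDITIONAL_PRODUCT = "conditional_product"


@dataclass(frozen=True)
class ProximityMatrix:
    """Symmetric entity x entity proximity in [0, 1] with unit diagonal."""

    s: pd.DataFrame
    formula: str  # COSINE | CONDITIONAL_PRODUCT

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.s.index)


@dataclass(frozen=True)
class SpaceGraph:
    """The backbone graph: MST plus threshold overlay.

    ``graph`` is an undirected networkx graph whose nodes carry ``score``
    (GSI for the indicator space, CSI for the country space), ``degree``
    and ``community`` attributes (and ``x``/``y`` once laid out); edges
    carry ``weight`` (proximity) and ``in_mst``.
    """

    graph: nx.Graph
    threshold: float

    @property
    def mst_edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted((u, v))) for u, v, d in self.graph.edges(data=True)
                if d["in_mst"]]

    def communities(self) -> dict[str, int]:
        return {n: d["community"] for n, d in self.graph.nodes(data=True)}

    def node_table(self) -> pd.DataFrame:
        rows = [{"node": n, **d} for n, d in sorted(self.graph.nodes(data=True))]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": min(u, v), "target": max(u, v), **d}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(sorted(rows, key=lambda r: (r["source"], r["target"])))


# ---------------------------------------------------------------------------
# Proximity
# ---------------------------------------------------------------------------

def proximity_matrix(m: BinaryAdvantageMatrix,
                     formula: str = COSINE) -> ProximityMatrix:
    """Pairwise proximity of indicator columns of M.

    ``cosine`` is co / sqrt(k_i k_j); ``conditional_product`` is
    co^2 / (k_i k_j), i.e. the cosine squared. Entities with zero ubiquity
    make the proximity undefined — prune first.
    """
    if formula not in (COSINE, CONDITIONAL_PRODUCT):
        raise ValueError(f"unknown proximity formula {formula!r}")
    mat = m.m.to_numpy(dtype=float)
    k = mat.sum(axis=0)
    if (k == 0).any():
        bad = m.m.columns[int(np.argmax(k == 0))]
        raise DegenerateInputError(
            f"entity {bad!r} has zero ubiquity; prune before building proximity")
    co = mat.T @ mat
    denom = np.sqrt(np.outer(k, k))
    cos = co / denom
    values = cos if formula == COSINE else cos ** 2
    np.fill_diagonal(values, 1.0)
    frame = pd.DataFrame(values, index=m.m.columns, columns=m.m.columns)
    return ProximityMatrix(s=frame, formula=formula)


def tradeoff_matrix(p: ProximityMatrix) -> ProximityMatrix:
    """Trade-off similarity 1 - S: high when two indicators are rarely
    co-specialized. Defined on the cosine proximity; an involution."""
    if p.formula != COSINE:
        raise DegenerateInputError("trade-off similarity is defined on the "
                                   "cosine proximity")
    return ProximityMatrix(s=1.0 - p.s, formula=COSINE)


# ---------------------------------------------------------------------------
# Maximum spanning tree (Kruskal, deterministic tie-break)
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, labels):
        self.parent = {x: x for x in labels}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def maximum_spanning_tree(p: ProximityMatrix,
                          allow_forest: bool = False
                          ) -> list[tuple[str, str, float]]:
    """Kruskal on descending weights; ties broken by lexicographic label
    pair, so the tree is deterministic even on the highly tied proximities
    that binary advantage matrices produce. Only strictly positive weights
    can enter the tree; a graph disconnected under positive weights raises
    with the component sizes, unless ``allow_forest`` is set, in which
    case the maximum spanning forest (one tree per component) is returned.
    The forest mode exists for the perfectly polarized limit, where the
    two indicator clusters share no co-specialization at all."""
    labels = list(p.s.index)
    values = p.s.to_numpy()
    edges = []
    for a, b in itertools.combinations(range(len(labels)), 2):
        w = float(values[a, b])
        if w > 0.0:
            la, lb = sorted((labels[a], labels[b]))
            edges.append((-w, la, lb))
    edges.sort()
    uf = _UnionFind(labels)
    tree = []
    for negw, la, lb in edges:
        if uf.union(la, lb):
            tree.append((la, lb, -negw))
            if len(tree) == len(labels) - 1:
                break
    if len(tree) != len(labels) - 1 and not allow_forest:
        roots = {}
        for lab in labels:
            roots.setdefault(uf.find(lab), []).append(lab)
        comps = sorted(roots.values(), key=len, reverse=True)
        raise DegenerateInputError(
            f"proximity graph is disconnected under positive weights: "
            f"{len(comps)} components, sizes {[len(c) for c in comps]}")
    return tree


# ---------------------------------------------------------------------------
# Space graph assembly
# ---------------------------------------------------------------------------

def build_space_graph(p: ProximityMatrix,
                      threshold: float = DEFAULT_THRESHOLD,
                      node_scores: pd.Series | None = None,
                      n_communities: int = 2,
                      allow_forest: bool = False) -> SpaceGraph:
    """Assemble the backbone graph: MST edges plus every pair with
    proximity >= ``threshold`` (inclusive). Node attributes ``score``,
    ``degree`` and ``community`` are populated; coordinates are added
    separately by :func:`layout_graph`.

    A proximity matrix disconnected under positive weights is an error by
    default; with ``allow_forest`` the backbone is the maximum spanning
    forest and the components themselves become the communities when they
    already number at least ``n_communities``."""
    if len(p.labels) < 2:
        raise DegenerateInputError("need at least 2 entities to build a space")
    tree = maximum_spanning_tree(p, allow_forest=allow_forest)
    g = nx.Graph()
    g.add_nodes_from(p.labels)
    for a, b, w in tree:
        g.add_edge(a, b, weight=w, in_mst=True)
    labels = list(p.s.index)
    values = p.s.to_numpy()
    for ia, ib in itertools.combinations(range(len(labels)), 2):
        w = float(values[ia, ib])
        if w >= threshold:
            a, b = sorted((labels[ia], labels[ib]))
            if g.has_edge(a, b):
                continue
            g.add_edge(a, b, weight=w, in_mst=False)
    if node_scores is not None:
        for node in g.nodes:
            g.nodes[node]["score"] = float(node_scores.get(node, np.nan))
    for node, deg in g.degree:
        g.nodes[node]["degree"] = int(deg)
    sg = SpaceGraph(graph=g, threshold=threshold)
    comms = detect_communities(sg, k=n_communities, node_scores=node_scores)
    for node, comm in comms.items():
        g.nodes[node]["community"] = comm
    return sg


def detect_communities(g: SpaceGraph, k: int = 2,
                       node_scores: pd.Series | None = None) -> dict[str, int]:
    """Girvan-Newman split into ``k`` communities.

    Repeatedly removes the edge of maximum unweighted betweenness
    centrality (ties: lexicographically smallest sorted pair) until the
    graph has ``k`` connected components. Communities are numbered so that
    community 1 has the higher mean node score (GSI/CSI); without scores
    they are numbered by size then smallest member.
    """
    graph = g.graph
    if k > graph.number_of_nodes():
        raise DegenerateInputError(
            f"cannot split {graph.number_of_nodes()} nodes into {k} communities")
    work = nx.Graph()
    work.add_nodes_from(graph.nodes)
    work.add_edges_from(graph.edges)
    while nx.number_connected_components(work) < k and work.number_of_edges():
        btw = nx.edge_betweenness_centrality(work, normalized=True)
        top_val = max(btw.values())
        tied = [tuple(sorted(e)) for e, v in btw.items()
                if abs(v - top_val) < 1e-12]
        work.remove_edge(*min(tied))
    components = [sorted(c) for c in nx.connected_components(work)]
    if node_scores is None and all("score" in graph.nodes[n] and
                                   np.isfinite(graph.nodes[n].get("score", np.nan))
                                   for n in graph.nodes):
        node_scores = pd.Series({n: graph.nodes[n]["score"] for n in graph.nodes})
    if node_scores is not None:
        def rank_key(comp):
            vals = [float(node_scores.get(n, np.nan)) for n in comp]
            vals = [v for v in vals if np.isfinite(v)]
            mean = np.mean(vals) if vals else -np.inf
            return (-mean, comp[0])
    else:
        def rank_key(comp):
            return (-len(comp), comp[0])
    components.sort(key=rank_key)
    return {node: idx + 1 for idx, comp in enumerate(components) for node in comp}


def layout_graph(g: SpaceGraph, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Deterministic 2-D Kamada-Kawai coordinates, scaled to the unit
    bounding box and written onto the nodes as ``x``/``y``.

    The optimization starts from a fixed circular arrangement of the
    sorted node list, so repeated calls (any seed) give identical output;
    ``seed`` is accepted for interface uniformity.
    """
    graph = g.graph
    nodes = sorted(graph.nodes)
    if len(nodes) == 1:
        coords = {nodes[0]: (0.5, 0.5)}
    else:
        angles = 2.0 * np.pi * np.arange(len(nodes)) / len(nodes)
        init = {n: (float(np.cos(a)), float(np.sin(a)))
                for n, a in zip(nodes, angles)}
        pos = nx.kamada_kawai_layout(graph, pos=init, weight=None)
        xs = np.array([pos[n][0] for n in nodes])
        ys = np.array([pos[n][1] for n in nodes])
        span_x = xs.max() - xs.min() or 1.0
        span_y = ys.max() - ys.min() or 1.0
        coords = {n: (float((pos[n][0] - xs.min()) / span_x),
                      float((pos[n][1] - ys.min()) / span_y)) for n in nodes}
    for n, (x, y) in coords.items():
        graph.nodes[n]["x"] = x
        graph.nodes[n]["y"] = y
    return coords


def country_space(m: BinaryAdvantageMatrix,
                  threshold: float = DEFAULT_THRESHOLD,
                  node_scores: pd.Series | None = None,
                  formula: str = COSINE,
                  allow_forest: bool = False) -> SpaceGraph:
    """The country-side space: the indicator pipeline applied to M
    transposed, with CSI as the node score."""
    if m.m.shape[0] < 2:
        raise DegenerateInputError("need at least 2 countries for a country space")
    transposed = BinaryAdvantageMatrix(m=m.m.T)
    p = proximity_matrix(transposed, formula=formula)
    return build_space_graph(p, threshold=threshold, node_scores=node_scores,
                             allow_forest=allow_forest)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_space(g: SpaceGraph, path, fmt: str = "graphml"):
    """Write the space graph as GraphML, GEXF, or a pair of CSV tables."""
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(g.graph, path)
    elif fmt == "gexf":
        nx.write_gexf(g.graph, path)
    elif fmt == "csv":
        from .io import write_table
        write_table(g.edge_table(), path.with_suffix(".edges.csv"))
        write_table(g.node_table(), path.with_suffix(".nodes.csv"))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
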