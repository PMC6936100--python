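"""Interactome construction and graph primitives.

The protein–protein interaction (PPI) network is held as an undirected
:class:`networkx.Graph` whose nodes are opaque gene identifier strings and
whose edges optionally carry a positive ``weight`` attribute.  All functions
that need a reproducible node ordering use the lexicographic order of the
node labels (``node_index``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "read_edge_list",
    "read_gmt",
    "write_edge_list",
    "write_gmt",
    "node_index",
    "largest_connected_component",
    "all_pairs_shortest_paths",
    "betweenness",
    "average_degree",
    "minimum_spanning_tree",
    "pathway_edge_weights",
]


class EdgeListParseError(ValueError):
    """Raised for malformed rows in an edge-list or association table."""


@dataclass
class DistanceMatrix:
    """All-pairs geodesic distances aligned to an ordered node index.

    Attributes
    ----------
    index : list of str
        Node labels in the order of the matrix rows/columns.
    values : ndarray of shape (n, n)
        Symmetric matrix of non-negative finite distances with zero diagonal.
    """

    index: list[str]
    values: np.ndarray
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"index of length {n}"
            )
        self._pos = {node: i for i, node in enumerate(self.index)}

    def loc(self, a: str, b: str) -> float:
        """Distance between two nodes by label."""
        return float(self.values[self._pos[a], self._pos[b]])

    def positions(self, nodes: Iterable[str]) -> np.ndarray:
        return np.array([self._pos[v] for v in nodes], dtype=int)

    def __len__(self) -> int:
        return len(self.index)


def node_index(g: nx.Graph) -> list[str]:
    """Canonical (lexicographic) node ordering used for all matrices."""
    return sorted(g.nodes)


def read_edge_list(path: str | Path, weighted: bool = False) -> nx.Graph:
    """Read an undirected edge list from a whitespace/tab separated file.

    Each non-comment line holds ``gene_a gene_b [weight]``.  Reversed
    duplicates are merged, self-loops are dropped with a warning, and the
    resulting graph is independent of row order.

    Parameters
    ----------
    path : str or Path
    weighted : bool
        If true, a third positive numeric column is read into the edge
        ``weight`` attribute (missing third column defaults to 1.0).

    Raises
    ------
    EdgeListParseError
        On rows with fewer than two columns or a malformed / non-positive
        weight; the error message names the offending line number.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(cols)}"
                )
            a, b = cols[0], cols[1]
            if a == b:
                logger.warning("%s: line %d: dropping self-loop on %r", path, lineno, a)
                g.add_node(a)
                continue
            w = 1.0
            if weighted and len(cols) >= 3:
                try:
                    w = float(cols[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: malformed weight {cols[2]!r}"
                    ) from exc
                if w <= 0:
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: non-positive weight {w}"
                    )
            if g.has_edge(a, b):
                logger.warning("%s: line %d: duplicate edge %r-%r ignored", path, lineno, a, b)
                continue
            if weighted:
                g.add_edge(a, b, weight=w)
            else:
                g.add_edge(a, b)
    return g


def write_edge_list(g: nx.Graph, path: str | Path, weighted: bool = False) -> None:
    """Write ``g`` as a sorted plain-text edge list (lexicographic rows)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            if weighted:
                w = g.edges[a, b].get("weight", 1.0)
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read pathway gene sets in GMT format (id, description, genes...).

    Returns a mapping pathway id -> set of gene identifiers.  Empty gene
    sets and duplicate pathway ids raise an error.
    """
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: GMT rows need id, description and >=1 gene"
                )
            pid = cols[0]
            if pid in pathways:
                raise EdgeListParseError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            genes = {c for c in cols[2:] if c}
            if not genes:
                raise EdgeListParseError(f"{path}: line {lineno}: pathway {pid!r} has no genes")
            pathways[pid] = genes
    return pathways


def write_gmt(pathways: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\tna\t{genes}\n")


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    PPI networks typically have one dominant component covering the vast
    majority of proteins; embedding requires a connected graph, so all
    downstream analysis is restricted to this component.  Ties in component
    size are broken by the smallest lexicographic node label.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot take the largest component of an empty graph")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    best = comps[0]
    return g.subgraph(best).copy()


def _check_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected; take largest_connected_component() first"
        )


def all_pairs_shortest_paths(g: nx.Graph, use_weights: bool = False) -> DistanceMatrix:
    """All-pairs geodesic distance matrix of a connected graph.

    Unweighted mode counts hops (BFS); weighted mode sums positive edge
    weights along a minimal path (Dijkstra).  Rows/columns follow
    :func:`node_index` order.
    """
    _check_connected(g)
    nodes = node_index(g)
    if use_weights:
        for _, _, w in g.edges(data="weight", default=1.0):
            if w <= 0:
                raise ValueError("all edge weights must be positive for weighted paths")
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    dist = csgraph.shortest_path(adj, method="auto", directed=False,
                                 unweighted=not use_weights)
    return DistanceMatrix(index=nodes, values=dist)


def betweenness(g: nx.Graph) -> dict[str, float]:
    """Raw (unnormalized) shortest-path betweenness centrality.

    c(u) = sum over unordered pairs {s, t}, s,t != u, of the fraction of
    shortest s–t paths passing through u.  Unweighted shortest paths.
    """
    _check_connected(g)
    return dict(nx.betweenness_centrality(g, normalized=False, weight=None))


def average_degree(g: nx.Graph, genes: Iterable[str]) -> float:
    """Mean number of incident edges over the given gene set."""
    genes = list(genes)
    if not genes:
        raise ValueError("average_degree: empty gene set")
    missing = [v for v in genes if v not in g]
    if missing:
        raise KeyError(f"genes not in graph: {missing[:5]}")
    return float(np.mean([g.degree[v] for v in genes]))


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(g: nx.Graph) -> nx.Graph:
    """Minimum spanning tree by Kruskal with lexicographic tie-breaking.

    Edges of equal weight are considered in lexicographic order of their
    (sorted) endpoint labels, so the returned tree is fully deterministic.
    Edge weights are carried over to the tree.
    """
    _check_connected(g)
    edges = sorted(
        ((g.edges[e].get("weight", 1.0),) + tuple(sorted(e)) for e in g.edges),
    )
    uf = _UnionFind(g.nodes)
    tree = nx.Graph()
    tree.add_nodes_from(g.nodes)
    for w, a, b in edges:
        if uf.union(a, b):
            tree.add_edge(a, b, weight=w)
            if tree.number_of_edges() == g.number_of_nodes() - 1:
                break
    return tree


def pathway_edge_weights(g: nx.Graph, pathways: Mapping[str, set[str]]) -> nx.Graph:
    """Reweight edges by pathway co-membership frequency.

    freq(e) counts the pathways containing both endpoints of edge e; the
    returned copy of ``g`` carries weight w(e) = 1 / (1 + freq(e)).  Edges
    whose endpoints never co-occur keep weight 1, while frequently
    co-annotated edges get weights close to 0 and are therefore
    preferentially selected by the *minimum* spanning tree.
    """
    freq: dict[tuple[str, str], int] = {}
    for genes in pathways.values():
        members = genes & set(g.nodes)
        for v in members:
            for u in g.neighbors(v):
                if u > v and u in members:
                    freq[(v, u)] = freq.get((v, u), 0) + 1
    out = g.copy()
    for a, b in out.edges:
        f = freq.get(tuple(sorted((a, b))), 0)
        out.edges[a, b]["weight"] = 1.0 / (1.0 + f)
        out.edges[a, b]["pathway_freq"] = f
    return out
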