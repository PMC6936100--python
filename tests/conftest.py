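"""Shared fixtures: tiny hand-checkable graphs and a small synthetic dataset."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import comorbnet as cn


@pytest.fixture
def path3() -> nx.Graph:
    """Path a-b-c: exactly 1-D embeddable with coordinates -1, 0, 1."""
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def weighted_triangle() -> nx.Graph:
    """Triangle with weights ab=1, bc=1, ac=10; MST = {ab, bc}."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("b", "c", weight=1.0)
    g.add_edge("a", "c", weight=10.0)
    return g


@pytest.fixture(scope="session")
def small_cfg() -> cn.SyntheticConfig:
    return cn.SyntheticConfig(
        n_nodes=300, n_pathways=60, pathway_size_range=(4, 12),
        n_pairs=50, module_size_range=(4, 10), n_shared_range=(2, 4), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(graph, disease-gene map, pairs, pathways) at fixture scale."""
    g = cn.generate_interactome(small_cfg)
    dgmap, pairs = cn.generate_disease_dataset(g, small_cfg)
    anchors = sorted(set().union(*(
        dgmap[p.disease_a] & dgmap[p.disease_b] for p in pairs if p.rr >= 1), set()))
    pathways = cn.generate_pathways(g, small_cfg, start_nodes=anchors)
    return g, dgmap, pairs, pathways


def random_connected_graph(rng: np.random.Generator, n_max: int = 7,
                           weighted: bool = False) -> nx.Graph:
    """Small random connected graph with letter labels (for oracles)."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: chr(97 + i) for i in range(n)})
    if weighted:
        for e in g.edges:
            g.edges[e]["weight"] = float(rng.integers(1, 6))
    return g


def enumerate_simple_path_distance(g: nx.Graph, s: str, t: str,
                                   use_weights: bool = False) -> float:
    """Shortest-path oracle by exhaustive simple-path enumeration."""
    if s == t:
        return 0.0
    best = np.inf

    def extend(node, seen, length):
        nonlocal best
        if node == t:
            best = min(best, length)
            return
        for u in g.neighbors(node):
            if u not in seen:
                w = g.edges[node, u].get("weight", 1.0) if use_weights else 1.0
                extend(u, seen | {u}, length + w)

    extend(s, {s}, 0.0)
    return best


def enumerate_all_shortest_paths(g: nx.Graph, s: str, t: str) -> list[tuple[str, ...]]:
    """All unweighted shortest s-t paths, by exhaustive enumeration."""
    paths: list[tuple[str, ...]] = []

    def extend(node, seen, path):
        if node == t:
            paths.append(tuple(path))
            return
        for u in g.neighbors(node):
            if u not in seen:
                extend(u, seen | {u}, path + [u])

    extend(s, {s}, [s])
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def brute_force_mst_weight(g: nx.Graph) -> float:
    """Minimum spanning-tree weight by enumerating all edge subsets."""
    n = g.number_of_nodes()
    best = np.inf
    edges = list(g.edges(data="weight", default=1.0))
    for subset in itertools.combinations(edges, n - 1):
        t = nx.Graph((a, b) for a, b, _ in subset)
        t.add_nodes_from(g.nodes)
        if nx.is_connected(t):
            best = min(best, sum(w for _, _, w in subset))
    return best


def brute_force_sab(g: nx.Graph, a: set[str], b: set[str]) -> float:
    """Nearest-neighbor module separation by direct per-pair BFS."""
    def dist(u, v):
        return nx.shortest_path_length(g, u, v)

    cross = []
    for v in a | b:
        if v in a and v in b:
            cross.append(0.0)
        else:
            other = b if v in a else a
            cross.append(min(dist(v, u) for u in other))
    d_ab = float(np.mean(cross))

    def within(mod):
        if len(mod) < 2:
            return 0.0
        return float(np.mean([min(dist(v, u) for u in mod if u != v) for v in mod]))

    return d_ab - (within(a) + within(b)) / 2.0
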