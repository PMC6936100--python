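"""Synthetic interactomes, pathway annotations and disease-pair datasets.

Real PPI networks are sparse, heavy-tailed and dominated by one connected
component; pathway gene sets are locally connected neighborhoods; and
comorbid disease pairs share genes and sit close together on the network.
The generators here plant exactly that structure so every pipeline stage is
testable end-to-end without external downloads:

* ``generate_interactome`` grows a preferential-attachment graph (connected
  by construction, power-law-ish degrees).
* ``generate_pathways`` takes random-walk node sets, so each pathway
  induces a connected subgraph; walks can be anchored at disease genes to
  emulate the enrichment of disease genes in curated pathways.
* ``generate_disease_dataset`` plants the comorbidity signal: comorbid
  pairs are grown from a common network neighborhood and share genes, with
  RR >= 1; their shared genes are drawn degree-biased, reflecting that
  genes associated with two diseases at once are pleiotropic and
  pleiotropic genes are interactome hubs.  Non-comorbid pairs get RR < 1
  (exactly 0 with probability 0.3, mirroring the point mass of zero-RR
  pairs in clinical comorbidity data); most are grown around seeds at
  least 4 hops apart and share nothing, but a fraction are *proximal*
  non-comorbid pairs that also share genes — network proximity correlates
  with comorbidity without determining it, so module separation alone is
  an imperfect predictor, as it is on clinical data.
* ``randomize_pair_genes`` is the degree-of-belief control: gene sets are
  replaced by random interactome genes while preserving each pair's module
  sizes and common-gene count exactly, destroying network locality only.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .diseases import DiseasePairRecord

__all__ = [
    "SyntheticConfig",
    "generate_interactome",
    "generate_pathways",
    "generate_disease_dataset",
    "randomize_pair_genes",
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-signal benchmark generator.

    Defaults define the benchmark conditions: a 2000-node scale-free-like
    interactome (attachment 2, mean degree ~4 as in sparse PPI maps), 400
    pathways of 5–30 genes (Reactome annotates ~2080 pathways over ~10,400
    proteins, i.e. about 0.2 pathways per protein, which at 2000 nodes
    scales to ~400), and 200 disease pairs, half comorbid.  Module sizes of
    8–25 genes bracket typical disease modules (for example 13 and 24 genes
    in the leprosy/lymphoma pair).  Comorbid modules share 3–6 genes drawn
    degree-biased from a common neighborhood and have relative risk in
    [1, 10]; non-comorbid pairs have RR in [0, 0.9] with a 0.3 point mass
    at exactly 0 (the zero-RR mass observed in clinical comorbidity tables
    is ~17% of all pairs, i.e. about a third of the non-comorbid ones).
    A fraction 0.3 of non-comorbid pairs are proximal look-alikes that
    share genes (drawn uniformly, not degree-biased); the rest are disjoint
    and seeded at least 4 hops apart.

    Comorbid pairs are seeded inside ``n_hotspots`` disease-dense
    neighborhoods (balls of radius ``hotspot_radius`` around well-separated
    hub anchors), while non-comorbid seeds are uniform over the graph.
    This plants the positional association between interactome location
    and comorbidity that geometric fingerprints exploit — the association
    that gene randomization (which preserves module sizes but scatters
    positions) destroys.
    """

    n_nodes: int = 2000
    attachment_edges: int = 2
    n_pathways: int = 400
    pathway_size_range: tuple[int, int] = (5, 30)
    n_pairs: int = 200
    frac_comorbid: float = 0.5
    module_size_range: tuple[int, int] = (8, 25)
    n_shared_range: tuple[int, int] = (3, 6)
    rr_comorbid_range: tuple[float, float] = (1.0, 10.0)
    rr_noncomorbid_range: tuple[float, float] = (0.05, 0.9)
    p_zero_rr: float = 0.3
    min_seed_distance: int = 4
    frac_proximal_noncomorbid: float = 0.3
    degree_biased_shared: bool = True
    n_hotspots: int = 3
    hotspot_radius: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_comorbid < 1:
            raise ValueError("frac_comorbid must be in (0, 1)")
        for lo, hi in (self.pathway_size_range, self.module_size_range,
                       self.n_shared_range):
            if lo > hi or lo < 1:
                raise ValueError("degenerate size range")
        if self.rr_comorbid_range[0] < 1:
            raise ValueError("comorbid RR range must start at >= 1")
        if not 0 < self.rr_noncomorbid_range[1] < 1:
            raise ValueError("non-comorbid RR range must stay below 1")
        if self.attachment_edges < 1:
            raise ValueError("attachment_edges must be >= 1")


def _node_label(i: int) -> str:
    return f"g{i:05d}"


def generate_interactome(cfg: SyntheticConfig) -> nx.Graph:
    """Preferential-attachment interactome, connected by construction.

    Starts from a path of ``attachment_edges`` nodes; each subsequent node
    attaches to ``attachment_edges`` distinct existing nodes chosen with
    probability proportional to degree, giving
    (a - 1) + (n - a) * a edges for attachment parameter a.
    """
    if cfg.n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    a = cfg.attachment_edges
    if a >= cfg.n_nodes:
        raise ValueError("attachment_edges must be < n_nodes")
    rng = np.random.default_rng([cfg.seed, 0])
    g = nx.Graph()
    nodes = [_node_label(i) for i in range(cfg.n_nodes)]
    g.add_nodes_from(nodes[:a])
    endpoints: list[str] = []       # degree-weighted sampling pool
    for i in range(a - 1):
        g.add_edge(nodes[i], nodes[i + 1])
        endpoints += [nodes[i], nodes[i + 1]]
    if a == 1:
        endpoints.append(nodes[0])  # lone seed node, degree 0: uniform pick
    for i in range(a, cfg.n_nodes):
        new = nodes[i]
        chosen: set[str] = set()
        while len(chosen) < a:
            chosen.add(endpoints[rng.integers(len(endpoints))])
        for t in sorted(chosen):
            g.add_edge(new, t)
            endpoints += [new, t]
    return g


def _random_walk_set(
    g: nx.Graph, start: str, length: int, rng: np.random.Generator
) -> set[str]:
    node = start
    visited = {node}
    for _ in range(length - 1):
        nbrs = sorted(g.neighbors(node))
        node = nbrs[rng.integers(len(nbrs))]
        visited.add(node)
    return visited


def generate_pathways(
    g: nx.Graph,
    cfg: SyntheticConfig,
    start_nodes: Sequence[str] | None = None,
    p_anchored: float = 0.5,
) -> dict[str, set[str]]:
    """Random-walk pathway gene sets (each induces a connected subgraph).

    When ``start_nodes`` is given, each walk starts from one of them with
    probability ``p_anchored`` (uniform over the graph otherwise), which
    makes pathways overlap disease modules the way curated pathways are
    enriched for disease genes.
    """
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("pathway generation requires a connected graph")
    rng = np.random.default_rng([cfg.seed, 1])
    nodes = sorted(g.nodes)
    anchors = sorted(set(start_nodes)) if start_nodes else []
    lo, hi = cfg.pathway_size_range
    pathways: dict[str, set[str]] = {}
    for i in range(cfg.n_pathways):
        length = int(rng.integers(lo, hi + 1))
        if anchors and rng.random() < p_anchored:
            start = anchors[rng.integers(len(anchors))]
        else:
            start = nodes[rng.integers(len(nodes))]
        pathways[f"PW{i:04d}"] = _random_walk_set(g, start, length, rng)
    return pathways


def _bfs_order(g: nx.Graph, source: str, skip: set[str] | None = None) -> list[str]:
    """Deterministic BFS node order (sorted neighbor expansion)."""
    skip = skip or set()
    seen = {source}
    order = [] if source in skip else [source]
    queue = [source]
    while queue:
        nxt = []
        for v in queue:
            for u in sorted(g.neighbors(v)):
                if u not in seen:
                    seen.add(u)
                    nxt.append(u)
                    if u not in skip:
                        order.append(u)
        queue = nxt
    return order


def _hotspots(
    g: nx.Graph, cfg: SyntheticConfig, rng: np.random.Generator
) -> list[str]:
    """Seed pool of the comorbidity hotspots: union of balls of radius
    ``hotspot_radius`` around ``n_hotspots`` well-separated, degree-biased
    anchor nodes."""
    nodes = sorted(g.nodes)
    deg = np.array([g.degree[v] for v in nodes], dtype=float)
    anchors: list[str] = []
    order = rng.choice(len(nodes), size=len(nodes), replace=False,
                       p=deg / deg.sum())
    for j in order:
        cand = nodes[j]
        if all(nx.shortest_path_length(g, cand, a) >= cfg.min_seed_distance
               for a in anchors):
            anchors.append(cand)
        if len(anchors) == cfg.n_hotspots:
            break
    pool: set[str] = set()
    for a in anchors:
        ball = nx.single_source_shortest_path_length(g, a,
                                                     cutoff=cfg.hotspot_radius)
        pool |= set(ball)
    return sorted(pool)


def _proximal_pair(
    g: nx.Graph,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    size_a: int,
    size_b: int,
    degree_biased: bool,
    seed_pool: list[str],
) -> tuple[set[str], set[str]]:
    """Two modules grown from one seed's BFS neighborhood, sharing genes.

    The seed is drawn uniformly from ``seed_pool``; the shared genes are
    sampled from the neighborhood pool with probability proportional to
    degree when ``degree_biased`` (pleiotropic shared genes), uniformly
    otherwise.
    """
    n_shared = int(rng.integers(cfg.n_shared_range[0], cfg.n_shared_range[1] + 1))
    n_shared = min(n_shared, size_a, size_b)
    need = size_a + size_b - n_shared
    seed_node = seed_pool[rng.integers(len(seed_pool))]
    pool = _bfs_order(g, seed_node)[:need]
    if len(pool) < need:
        raise ValueError("graph too small for requested module sizes")
    if degree_biased:
        deg = np.array([g.degree[v] for v in pool], dtype=float)
        shared_idx = rng.choice(len(pool), size=n_shared, replace=False,
                                p=deg / deg.sum())
    else:
        shared_idx = rng.choice(len(pool), size=n_shared, replace=False)
    shared = {pool[j] for j in shared_idx}
    rest = [pool[j] for j in rng.permutation(len(pool)) if pool[j] not in shared]
    genes_a = shared | set(rest[:size_a - n_shared])
    genes_b = shared | set(rest[size_a - n_shared:need - n_shared])
    return genes_a, genes_b


def generate_disease_dataset(
    g: nx.Graph,
    cfg: SyntheticConfig,
) -> tuple[dict[str, set[str]], list[DiseasePairRecord]]:
    """Disease–gene map and pair table with planted comorbidity structure.

    Comorbid pairs (fraction ``frac_comorbid``): both modules are drawn
    from the breadth-first neighborhood of one seed node and forced to
    share ``n_shared`` genes sampled degree-biased (pleiotropy); RR is
    uniform in ``rr_comorbid_range``.  Non-comorbid pairs: RR is 0 with
    probability ``p_zero_rr`` and otherwise uniform in
    ``rr_noncomorbid_range``; a fraction ``frac_proximal_noncomorbid`` of
    them are proximal look-alikes built like comorbid pairs but with
    uniformly sampled shared genes, and the rest are disjoint modules
    grown around two seeds at graph distance >= ``min_seed_distance``.
    Disease names are unique per pair.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    nodes = sorted(g.nodes)
    hotspot_pool = _hotspots(g, cfg, rng)
    n_com = round(cfg.n_pairs * cfg.frac_comorbid)
    dgmap: dict[str, set[str]] = {}
    pairs: list[DiseasePairRecord] = []
    lo_m, hi_m = cfg.module_size_range
    for i in range(cfg.n_pairs):
        comorbid = i < n_com
        size_a = int(rng.integers(lo_m, hi_m + 1))
        size_b = int(rng.integers(lo_m, hi_m + 1))
        if comorbid:
            genes_a, genes_b = _proximal_pair(
                g, cfg, rng, size_a, size_b,
                degree_biased=cfg.degree_biased_shared,
                seed_pool=hotspot_pool)
            rr = float(rng.uniform(*cfg.rr_comorbid_range))
        else:
            rr = 0.0 if rng.random() < cfg.p_zero_rr else float(
                rng.uniform(*cfg.rr_noncomorbid_range))
            if rng.random() < cfg.frac_proximal_noncomorbid:
                genes_a, genes_b = _proximal_pair(
                    g, cfg, rng, size_a, size_b, degree_biased=False,
                    seed_pool=nodes)
            else:
                seed_a = nodes[rng.integers(len(nodes))]
                hops = nx.single_source_shortest_path_length(g, seed_a)
                far = sorted(v for v, h in hops.items()
                             if h >= cfg.min_seed_distance)
                if not far:
                    raise ValueError(
                        f"no node at distance >= {cfg.min_seed_distance} "
                        f"from {seed_a!r}"
                    )
                seed_b = far[rng.integers(len(far))]
                genes_a = set(_bfs_order(g, seed_a)[:size_a])
                genes_b = set(_bfs_order(g, seed_b, skip=genes_a)[:size_b])
        da, db = f"D{i:04d}a", f"D{i:04d}b"
        dgmap[da], dgmap[db] = genes_a, genes_b
        pairs.append(DiseasePairRecord(da, db, rr))
    return dgmap, pairs


def randomize_pair_genes(
    dgmap: Mapping[str, set[str]],
    pairs: Sequence[DiseasePairRecord],
    g: nx.Graph,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Randomization control: random gene sets with preserved cardinalities.

    For every pair, the two modules are replaced by uniformly random
    interactome genes such that |A|, |B| and |A ∩ B| are preserved exactly.
    Diseases not touched by ``pairs`` keep their original gene sets; a
    disease appearing in several pairs takes the sets of its last pair.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    out = {k: set(v) for k, v in dgmap.items()}
    for p in pairs:
        a, b = dgmap[p.disease_a], dgmap[p.disease_b]
        n_shared = len(a & b)
        total = len(a) + len(b) - n_shared
        if total > len(nodes):
            raise ValueError("modules larger than the interactome")
        draw = list(rng.choice(nodes, size=total, replace=False))
        shared = set(draw[:n_shared])
        new_a = shared | set(draw[n_shared:len(a)])
        new_b = shared | set(draw[len(a):total])
        out[p.disease_a], out[p.disease_b] = new_a, new_b
    return out
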