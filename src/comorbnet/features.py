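"""Per-pair feature vectors for comorbidity classification.

Each disease pair is fingerprinted by m + 3 numbers: the projection of its
combined gene module onto each of the m embedding axes (the sum of module
gene coordinates per axis), plus three topological summaries of the module
on the raw interactome — mean degree, mean betweenness centrality, and the
mean number of annotated pathways per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import network
from .diseases import DiseasePairRecord
from .embedding import Embedding

__all__ = [
    "FeatureVector",
    "module_projection",
    "gene_pathway_counts",
    "pair_feature_vector",
    "build_feature_table",
    "feature_columns",
    "common_gene_pathway_profile",
]


@dataclass
class FeatureVector:
    """(m + 3)-dimensional fingerprint of one disease pair."""

    pair: DiseasePairRecord
    f: np.ndarray            # m geometric projections
    avg_degree: float
    avg_centrality: float
    avg_pathways: float

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [self.f, [self.avg_degree, self.avg_centrality, self.avg_pathways]]
        )

    def __len__(self) -> int:
        return self.f.shape[0] + 3


def module_projection(e: Embedding, genes: Iterable[str]) -> np.ndarray:
    """Projection of a gene module onto each embedding axis.

    f_i = sum over module genes g of z_i(g); the empty module projects to
    the zero vector.
    """
    genes = list(genes)
    if not genes:
        return np.zeros(e.m)
    return e.rows(genes).sum(axis=0)


def gene_pathway_counts(pathways: Mapping[str, set[str]]) -> dict[str, int]:
    """Number of pathways each gene belongs to (genes absent -> 0 implied)."""
    counts: dict[str, int] = {}
    for genes in pathways.values():
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def pair_feature_vector(
    e: Embedding,
    g: nx.Graph,
    pathways: Mapping[str, set[str]],
    pair: DiseasePairRecord,
    dgmap: Mapping[str, set[str]],
    centrality: Mapping[str, float] | None = None,
    pathway_counts: Mapping[str, int] | None = None,
) -> FeatureVector:
    """Assemble the (m + 3)-feature fingerprint of one disease pair.

    The pair module is the union of the two diseases' gene sets (shared
    genes counted once); it is invariant to the order of the diseases.
    ``centrality`` and ``pathway_counts`` may be precomputed once per graph
    and reused across pairs — betweenness is by far the most expensive step.
    """
    for disease in (pair.disease_a, pair.disease_b):
        if disease not in dgmap:
            raise KeyError(f"disease {disease!r} missing from disease-gene map")
    module = sorted(dgmap[pair.disease_a] | dgmap[pair.disease_b])
    if centrality is None:
        centrality = network.betweenness(g)
    if pathway_counts is None:
        pathway_counts = gene_pathway_counts(pathways)
    return FeatureVector(
        pair=pair,
        f=module_projection(e, module),
        avg_degree=network.average_degree(g, module),
        avg_centrality=float(np.mean([centrality[v] for v in module])),
        avg_pathways=float(np.mean([pathway_counts.get(v, 0) for v in module])),
    )


def build_feature_table(
    e: Embedding,
    g: nx.Graph,
    pathways: Mapping[str, set[str]],
    pairs: Sequence[DiseasePairRecord],
    dgmap: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Feature matrix for a list of disease pairs.

    Columns: disease_a, disease_b, rr, f_1 ... f_m, avg_degree,
    avg_centrality, avg_pathways.  Betweenness and pathway counts are
    computed once and shared.
    """
    centrality = network.betweenness(g)
    counts = gene_pathway_counts(pathways)
    rows = []
    for p in pairs:
        fv = pair_feature_vector(e, g, pathways, p, dgmap,
                                 centrality=centrality, pathway_counts=counts)
        row: dict[str, object] = {"disease_a": p.disease_a, "disease_b": p.disease_b,
                                  "rr": p.rr}
        for j, x in enumerate(fv.f, start=1):
            row[f"f_{j}"] = x
        row["avg_degree"] = fv.avg_degree
        row["avg_centrality"] = fv.avg_centrality
        row["avg_pathways"] = fv.avg_pathways
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns of a feature table."""
    return [c for c in table.columns if c.startswith("f_")] + [
        "avg_degree", "avg_centrality", "avg_pathways"]


def common_gene_pathway_profile(
    pairs: Sequence[DiseasePairRecord],
    dgmap: Mapping[str, set[str]],
    pathways: Mapping[str, set[str]],
    g: nx.Graph | None = None,
    randomize: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Pathway burden of the genes shared by each disease pair.

    For every pair, counts the pathways containing at least one of the
    pair's common genes.  With ``randomize`` the common genes are first
    replaced by uniformly random interactome genes (preserving the
    common-gene count per pair), which serves as the null profile: random
    gene sets tend to scatter across *more* pathways than real shared
    disease genes.
    """
    if randomize and g is None:
        raise ValueError("randomize=True requires the interactome g")
    rng = np.random.default_rng(seed)
    pool = sorted(g.nodes) if g is not None else []
    rows = []
    for p in pairs:
        common = sorted(dgmap[p.disease_a] & dgmap[p.disease_b])
        if randomize and common:
            common = list(rng.choice(pool, size=len(common), replace=False))
        n_pw = sum(1 for genes in pathways.values() if genes.intersection(common))
        rows.append({"disease_a": p.disease_a, "disease_b": p.disease_b,
                     "n_common_genes": len(common), "n_pathways": n_pw})
    return pd.DataFrame(rows)
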