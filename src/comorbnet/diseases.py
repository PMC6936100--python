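"""Disease–gene associations and the module-separation baseline.

A disease module is the set of genes associated with a disease, viewed as a
subgraph of the interactome.  The network-based separation of two modules,

    S_AB = <d_AB> - (<d_AA> + <d_BB>) / 2,

compares the mean cross-module nearest-neighbor distance <d_AB> with the
mean within-module nearest-neighbor distances.  Negative S_AB means the two
modules overlap topologically, which correlates with comorbidity; the
baseline predictor therefore ranks disease pairs by -S_AB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .network import DistanceMatrix, EdgeListParseError

logger = logging.getLogger(__name__)

__all__ = [
    "DiseasePairRecord",
    "load_disease_gene_map",
    "load_pair_table",
    "write_disease_gene_map",
    "write_pair_table",
    "module_separation",
    "sab_baseline_scores",
]


@dataclass
class DiseasePairRecord:
    """One disease pair with its comorbidity relative risk.

    ``rr`` is the relative risk from clinical co-occurrence (RR > 1 means
    the diseases co-occur more than expected by chance); ``s_ab`` is filled
    in when the module separation has been computed.
    """

    disease_a: str
    disease_b: str
    rr: float
    s_ab: float | None = None

    def __post_init__(self) -> None:
        if self.disease_a == self.disease_b:
            raise ValueError(f"disease pair with identical members: {self.disease_a!r}")
        if self.rr < 0:
            raise ValueError(f"negative relative risk {self.rr}")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.disease_a, self.disease_b)))  # type: ignore[return-value]


def load_disease_gene_map(path: str | Path, g: nx.Graph) -> dict[str, set[str]]:
    """Read a two-column (disease, gene) TSV restricted to the interactome.

    Genes absent from ``g`` are dropped (a per-disease count is logged) and
    diseases left without any mapped gene are removed with a warning.
    Duplicate rows collapse to a single membership.
    """
    raw: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected (disease, gene), got {len(cols)} column(s)"
                )
            raw.setdefault(cols[0], set()).add(cols[1])
    nodes = set(g.nodes)
    out: dict[str, set[str]] = {}
    for disease, genes in raw.items():
        kept = genes & nodes
        dropped = len(genes) - len(kept)
        if dropped:
            logger.info("disease %r: dropped %d gene(s) absent from the interactome",
                        disease, dropped)
        if not kept:
            logger.warning("disease %r has no genes in the interactome; removed", disease)
            continue
        out[disease] = kept
    return out


def write_disease_gene_map(dgmap: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for disease in sorted(dgmap):
            for gene in sorted(dgmap[disease]):
                fh.write(f"{disease}\t{gene}\n")


def load_pair_table(path: str | Path) -> list[DiseasePairRecord]:
    """Read a (disease_a, disease_b, rr) TSV into pair records."""
    pairs: list[DiseasePairRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if cols[:3] == ["disease_a", "disease_b", "rr"]:
                continue  # header
            if len(cols) < 3:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected (disease_a, disease_b, rr)"
                )
            try:
                rr = float(cols[2])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: malformed RR value {cols[2]!r}"
                ) from exc
            pairs.append(DiseasePairRecord(cols[0], cols[1], rr))
    return pairs


def write_pair_table(pairs: Iterable[DiseasePairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_a\tdisease_b\trr\n")
        for p in pairs:
            fh.write(f"{p.disease_a}\t{p.disease_b}\t{p.rr:.10g}\n")


def _nearest_cross(d: DistanceMatrix, a: set[str], b: set[str]) -> float:
    """<d_AB>: mean over genes of A ∪ B of the distance to the nearest gene
    of the *other* module (0 for genes shared by both)."""
    ia = d.positions(sorted(a))
    ib = d.positions(sorted(b))
    vals = []
    for gene in sorted(a | b):
        if gene in a and gene in b:
            vals.append(0.0)
            continue
        i = d.positions([gene])[0]
        other = ib if gene in a else ia
        vals.append(float(d.values[i, other].min()))
    return float(np.mean(vals))


def _nearest_within(d: DistanceMatrix, a: set[str]) -> float:
    """<d_AA>: mean distance of each gene to its nearest *other* module gene;
    0 for a singleton module by convention."""
    if len(a) < 2:
        return 0.0
    idx = d.positions(sorted(a))
    sub = d.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def module_separation(
    d: DistanceMatrix,
    genes_a: set[str],
    genes_b: set[str],
    variant: str = "nearest",
) -> float:
    """Network separation S_AB of two disease modules.

    Parameters
    ----------
    d : DistanceMatrix
        All-pairs geodesic distances on the interactome component.
    genes_a, genes_b : set of str
        Non-empty modules, subsets of ``d.index``.
    variant : {"nearest", "mean"}
        ``nearest`` (default) uses nearest-neighbor distances as in the
        standard network-separation statistic; ``mean`` uses plain all-pairs
        mean distances (within-module mean over unordered pairs), kept for
        sensitivity analysis.
    """
    if not genes_a or not genes_b:
        raise ValueError("module_separation: empty module")
    a, b = set(genes_a), set(genes_b)
    if variant == "nearest":
        dab = _nearest_cross(d, a, b)
        daa = _nearest_within(d, a)
        dbb = _nearest_within(d, b)
    elif variant == "mean":
        ia, ib = d.positions(sorted(a)), d.positions(sorted(b))
        dab = float(d.values[np.ix_(ia, ib)].mean())
        daa = _mean_within(d, ia)
        dbb = _mean_within(d, ib)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return dab - (daa + dbb) / 2.0


def _mean_within(d: DistanceMatrix, idx: np.ndarray) -> float:
    if len(idx) < 2:
        return 0.0
    sub = d.values[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))  # mean over ordered pairs = unordered mean


def sab_baseline_scores(
    pairs: Sequence[DiseasePairRecord],
    d: DistanceMatrix,
    dgmap: Mapping[str, set[str]],
    variant: str = "nearest",
) -> dict[tuple[str, str], float]:
    """Baseline comorbidity score -S_AB per disease pair.

    Smaller (more negative) separation means more overlapping modules and
    hence higher predicted comorbidity, so the score is the negated S_AB;
    the result is symmetric in the two diseases and suitable as a ROC score
    against RR-derived labels.  The computed S_AB is also stored on each
    record.
    """
    scores: dict[tuple[str, str], float] = {}
    for p in pairs:
        for disease in (p.disease_a, p.disease_b):
            if disease not in dgmap:
                raise KeyError(f"disease {disease!r} missing from disease-gene map")
        s = module_separation(d, dgmap[p.disease_a], dgmap[p.disease_b], variant=variant)
        p.s_ab = s
        scores[p.key] = -s
    return scores
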