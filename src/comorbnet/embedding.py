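"""Geometric embedding of the interactome.

Three spectral embeddings of the all-pairs geodesic distance matrix are
provided:

``mds``
    Classical multidimensional scaling on shortest-path distances
    (Isomap-style): square the distances, double-center to a Gram matrix
    A = -1/2 J D^2 J, and take the top-m eigenpairs, X = E_m Lambda_m^{1/2}.
``mce``
    Centered minimum curvilinear embedding: the same spectral machinery
    applied to *minimum curvilinear* distances, i.e. path lengths measured
    along the graph's minimum spanning tree.  The MST acts as a nonlinear
    skeleton of the network, so MCE captures hierarchical structure that
    plain MDS smooths away.
``ncmce``
    Non-centered MCE: singular value decomposition applied directly to the
    minimum curvilinear distance matrix (no double centering),
    X = U_m Sigma_m^{1/2}.

Graph distances are generally non-Euclidean, so the Gram matrix can have
negative eigenvalues; these are clamped to zero (with a warning) before the
square root.  Eigenvector signs are canonicalized (first non-zero entry of
each axis positive) so repeated runs and node reorderings give identical
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .network import (
    DistanceMatrix,
    all_pairs_shortest_paths,
    minimum_spanning_tree,
    node_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GramMatrix",
    "Embedding",
    "double_center",
    "eigen_embed",
    "minimum_curvilinear_distances",
    "embed_mds",
    "embed_mce",
    "embed_ncmce",
    "reconstruction_error",
    "write_embedding",
    "read_embedding",
]


@dataclass
class GramMatrix:
    """Double-centered inner-product matrix aligned to a node index."""

    index: list[str]
    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.index)
        if self.a.shape != (n, n):
            raise ValueError("Gram matrix shape does not match index")


@dataclass
class Embedding:
    """n x m coordinate matrix with the retained spectrum.

    Attributes
    ----------
    index : list of str
        Node labels, one per coordinate row, in lexicographic graph order.
    coords : ndarray (n, m)
        Coordinates; column j scales eigenvector j by sqrt(eigenvalue j).
    eigenvalues : ndarray (m,)
        Retained eigenvalues (singular values for ``ncmce``), non-increasing.
    method : str
        One of ``mds``, ``mce``, ``ncmce``.
    weighted : bool
        Whether edge weights entered the distance computation.
    """

    index: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    method: str
    weighted: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.shape[0] != len(self.index):
            raise ValueError("coordinate rows do not match index")
        if self.coords.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("eigenvalue count does not match dimension")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        self._pos = {v: i for i, v in enumerate(self.index)}

    @property
    def m(self) -> int:
        return self.coords.shape[1]

    def rows(self, nodes) -> np.ndarray:
        """Coordinate rows for the given node labels."""
        try:
            idx = [self._pos[v] for v in nodes]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in embedding") from None
        return self.coords[idx]


def double_center(d: DistanceMatrix) -> GramMatrix:
    """Convert squared distances to a Gram matrix: A = -1/2 J D^2 J.

    J = I - n^{-1} 1 1' is the centering projector; the result is symmetric
    with rows and columns summing to zero.
    """
    s = d.values ** 2
    row = s.mean(axis=1, keepdims=True)
    col = s.mean(axis=0, keepdims=True)
    grand = s.mean()
    a = -0.5 * (s - row - col + grand)
    a = (a + a.T) / 2.0  # kill rounding asymmetry
    return GramMatrix(index=list(d.index), a=a)


def _canonicalize_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its first non-zero entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def eigen_embed(a: GramMatrix, m: int) -> Embedding:
    """Top-m spectral coordinates of a Gram matrix.

    Eigenvalues are sorted in non-increasing order; coordinates are
    X[:, j] = e_j * sqrt(max(lambda_j, 0)).  Negative eigenvalues (the
    distance matrix was not exactly Euclidean) are clamped to zero with a
    warning.
    """
    n = len(a.index)
    if not 1 <= m <= n:
        raise ValueError(f"embedding dimension m={m} must satisfy 1 <= m <= n={n}")
    vals, vecs = scipy.linalg.eigh(a.a, subset_by_index=[n - m, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals < -1e-10):
        logger.warning(
            "clamping %d negative eigenvalue(s) (min %.3g) to zero",
            int(np.sum(vals < -1e-10)), float(vals.min()),
        )
    clamped = np.clip(vals, 0.0, None)
    vecs = _canonicalize_signs(vecs)
    coords = vecs * np.sqrt(clamped)
    return Embedding(index=list(a.index), coords=coords, eigenvalues=vals,
                     method="mds", weighted=False)


def minimum_curvilinear_distances(g: nx.Graph, use_weights: bool = False) -> DistanceMatrix:
    """All-pairs path lengths measured along the minimum spanning tree.

    With ``use_weights`` the MST is built from, and path lengths sum, the
    graph's edge weights; otherwise both use unit weights.
    """
    tree = minimum_spanning_tree(g)
    return all_pairs_shortest_paths(tree, use_weights=use_weights)


def embed_mds(g: nx.Graph, m: int, use_weights: bool = False) -> Embedding:
    """Isomap-style classical MDS of the graph's geodesic distances."""
    d = all_pairs_shortest_paths(g, use_weights=use_weights)
    emb = eigen_embed(double_center(d), m)
    emb.method = "mds"
    emb.weighted = use_weights
    return emb


def embed_mce(g: nx.Graph, m: int, use_weights: bool = False) -> Embedding:
    """Centered minimum curvilinear embedding (MDS over MST distances)."""
    d = minimum_curvilinear_distances(g, use_weights=use_weights)
    emb = eigen_embed(double_center(d), m)
    emb.method = "mce"
    emb.weighted = use_weights
    return emb


def embed_ncmce(g: nx.Graph, m: int, use_weights: bool = False) -> Embedding:
    """Non-centered MCE: truncated SVD of the MC distance matrix itself."""
    d = minimum_curvilinear_distances(g, use_weights=use_weights)
    n = len(d.index)
    if not 1 <= m <= n:
        raise ValueError(f"embedding dimension m={m} must satisfy 1 <= m <= n={n}")
    u, s, _ = np.linalg.svd(d.values, full_matrices=False)
    u = _canonicalize_signs(u[:, :m])
    coords = u * np.sqrt(s[:m])
    return Embedding(index=list(d.index), coords=coords, eigenvalues=s[:m],
                     method="ncmce", weighted=use_weights)


def reconstruction_error(e: Embedding, d: DistanceMatrix) -> float:
    """RMS mismatch between embedded Euclidean and target distances.

    Root-mean-square of |d_embedded(i,j) - d(i,j)| over all unordered node
    pairs; 0 means the m-dimensional configuration reproduces the input
    distances exactly.
    """
    if list(e.index) != list(d.index):
        raise ValueError("embedding and distance matrix indexes differ")
    emb_d = pdist(e.coords)
    target = squareform(d.values, checks=False)
    if emb_d.size == 0:
        return 0.0
    return float(np.sqrt(np.mean((emb_d - target) ** 2)))


def write_embedding(e: Embedding, path: str | Path) -> None:
    """Persist coordinates as TSV plus a ``<path>.meta`` key=value sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        dims = "\t".join(f"dim_{j + 1}" for j in range(e.m))
        fh.write(f"gene\t{dims}\n")
        for i, v in enumerate(e.index):
            row = "\t".join(f"{x:.10g}" for x in e.coords[i])
            fh.write(f"{v}\t{row}\n")
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        fh.write(f"method={e.method}\n")
        fh.write(f"weighted={int(e.weighted)}\n")
        fh.write(f"m={e.m}\n")
        fh.write("eigenvalues=" + ",".join(f"{x:.10g}" for x in e.eigenvalues) + "\n")


def read_embedding(path: str | Path) -> Embedding:
    path = Path(path)
    index: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene\t"):
            raise ValueError(f"{path}: not an embedding table")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            index.append(cols[0])
            rows.append([float(x) for x in cols[1:]])
    meta = {"method": "mds", "weighted": "0", "eigenvalues": ""}
    meta_path = path.with_suffix(path.suffix + ".meta")
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k] = v
    coords = np.array(rows)
    if meta["eigenvalues"]:
        eig = np.array([float(x) for x in meta["eigenvalues"].split(",")])
    else:
        eig = np.full(coords.shape[1], np.nan)
    return Embedding(index=index, coords=coords, eigenvalues=eig,
                     method=meta["method"], weighted=bool(int(meta["weighted"])))
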