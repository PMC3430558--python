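"""Navigation maps: classical MDS over pairwise descriptor distances.

The database is embedded into 2 or 3 dimensions so that Euclidean
distances between embedded molecules approximate 1 - similarity of
their descriptors.  Classical (Torgerson) scaling is used: the squared
dissimilarity matrix is double-centered, the top-d eigenpairs give the
coordinates, so the result is deterministic.  Conformational groups are
assigned colors from a fixed palette for the exported maps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .retrieval import Index, similarity

logger = logging.getLogger(__name__)

# Qualitative palette (matplotlib "tab20" hex values), cycled by group order.
PALETTE = [
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c", "#98df8a",
    "#d62728", "#ff9896", "#9467bd", "#c5b0d5", "#8c564b", "#c49c94",
    "#e377c2", "#f7b6d2", "#7f7f7f", "#c7c7c7", "#bcbd22", "#dbdb8d",
    "#17becf", "#9edae5",
]


@dataclass
class Embedding:
    """Low-dimensional navigation coordinates for an indexed database."""

    coordinates: np.ndarray  # (n, d), d in {2, 3}
    ids: list[str]
    groups: list[str] = field(default_factory=list)
    stress: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[1] not in (2, 3):
            raise ValueError("embedding dimension must be 2 or 3")
        if len(self.ids) != len(self.coordinates):
            raise ValueError("one coordinate row per molecule id required")
        if self.stress < 0:
            raise ValueError("stress must be non-negative")

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]

    def colors(self) -> list[str]:
        """Deterministic per-molecule colors: palette indexed by group order."""
        order: dict[str, int] = {}
        for g in self.groups:
            if g not in order:
                order[g] = len(order)
        return [PALETTE[order[g] % len(PALETTE)] for g in self.groups]


def distance_matrix(index: Index, method: str) -> np.ndarray:
    """Symmetric zero-diagonal matrix of 1 - similarity over the index."""
    ids = index.ids
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        di = index[ids[i]].descriptors[method]
        for j in range(i + 1, n):
            dj = index[ids[j]].descriptors[method]
            D[i, j] = D[j, i] = 1.0 - similarity(di, dj).value
    return D


def _stress(D: np.ndarray, X: np.ndarray) -> float:
    """Kruskal-type raw stress: sqrt(sum (dhat - d)^2 / sum d^2)."""
    diff = X[:, None, :] - X[None, :, :]
    Dhat = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(D), k=1)
    denom = float((D[iu] ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((Dhat[iu] - D[iu]) ** 2).sum() / denom))


def mds_embed(
    D: np.ndarray,
    dim: int = 2,
    *,
    ids: list[str] | None = None,
    groups: list[str] | None = None,
) -> Embedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers -1/2 J D^2 J, takes the top-``dim`` eigenpairs with
    non-negative eigenvalues, and fixes each axis's sign so that its
    largest-magnitude coordinate is positive.  If fewer than ``dim``
    positive eigenvalues exist, the remaining axes are zero-padded with
    a warning.
    """
    D = np.asarray(D, dtype=float)
    if dim not in (2, 3):
        raise ValueError("embedding dimension must be 2 or 3")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int(np.sum(eigvals[:dim] > 1e-12))
    if n_pos < dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); padding {dim - n_pos} "
            "zero axis/axes", stacklevel=2,
        )
    X = np.zeros((n, dim))
    take = eigvals[:n_pos]
    X[:, :n_pos] = eigvecs[:, :n_pos] * np.sqrt(take)
    # Deterministic orientation: the largest-magnitude entry of every axis
    # points in the positive direction.
    for a in range(dim):
        col = X[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            X[:, a] = -col
    ids = ids if ids is not None else [str(i) for i in range(n)]
    groups = groups if groups is not None else [""] * n
    return Embedding(coordinates=X, ids=list(ids), groups=list(groups),
                     stress=_stress(D, X))


def embed_index(index: Index, method: str, dim: int = 2) -> Embedding:
    """MDS navigation map of an index under one descriptor method."""
    D = distance_matrix(index, method)
    ids = index.ids
    groups = [index[i].group for i in ids]
    return mds_embed(D, dim, ids=ids, groups=groups)


def export_navigation(embedding: Embedding, out_prefix: str) -> dict[str, str]:
    """Write the navigation map as CSV and JSON.

    Produces ``<prefix>.csv`` with columns id, group, x, y[, z], color
    and ``<prefix>.json`` with the same records plus the stress value.
    Returns the written paths.
    """
    cols = ["x", "y", "z"][: embedding.dim]
    df = pd.DataFrame(embedding.coordinates, columns=cols)
    df.insert(0, "id", embedding.ids)
    df.insert(1, "group", embedding.groups)
    df["color"] = embedding.colors()
    csv_path = f"{out_prefix}.csv"
    json_path = f"{out_prefix}.json"
    df.to_csv(csv_path, index=False)
    payload = {
        "dim": embedding.dim,
        "stress": embedding.stress,
        "records": [
            {
                "id": embedding.ids[i],
                "group": embedding.groups[i],
                "coords": [float(c) for c in embedding.coordinates[i]],
                "color": df["color"].iloc[i],
            }
            for i in range(len(embedding.ids))
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"csv": csv_path, "json": json_path}
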