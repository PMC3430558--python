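"""Surface sampling and inner-distance computation.

The inner distance between two landmark points is the length of the
shortest path connecting them that stays inside the molecular volume.
Here the volume is a voxel lattice; paths run through the full occupied
set (interior voxels included) on the 26-connected neighbor graph whose
edge weights are the Euclidean center-to-center distances h, h*sqrt(2),
h*sqrt(3).  Landmarks are surface voxels spread approximately uniformly
by Lloyd's relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .molio import SurfaceVoxels, VoxelGrid

#: The 13 positive-lexicographic neighbor offsets of 26-connectivity
#: (each undirected edge counted once).
_HALF_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
)


@dataclass
class SamplePoints:
    """Landmark surface voxels chosen by Lloyd relaxation."""

    indices: np.ndarray  # (n, 3) lattice coordinates, pairwise distinct
    grid: VoxelGrid = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.indices)

    def centers(self) -> np.ndarray:
        return self.grid.centers(self.indices)


@dataclass
class VoxelGraph:
    """Weighted 26-connectivity graph over the occupied voxels.

    ``node_index`` maps a lattice coordinate to its row in the sparse
    adjacency matrix; ``nodes`` is the inverse mapping.
    """

    nodes: np.ndarray  # (n, 3) lattice coordinates
    adjacency: csr_matrix
    h: float
    grid: VoxelGrid = field(repr=False)

    def __post_init__(self) -> None:
        self._lookup = {tuple(v): i for i, v in enumerate(np.asarray(self.nodes))}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def node_id(self, voxel) -> int:
        key = tuple(int(c) for c in voxel)
        if key not in self._lookup:
            raise KeyError(f"voxel {key} is not an occupied graph node")
        return self._lookup[key]


@dataclass
class InnerDistanceSet:
    """All-pairs inner distances over a landmark set."""

    values: np.ndarray  # (n*(n-1)/2,) Angstrom, condensed order
    n_points: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_points * (self.n_points - 1) // 2
        if len(self.values) != expected:
            raise ValueError(
                f"expected {expected} pair distances for n={self.n_points}, "
                f"got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)


def build_voxel_graph(grid: VoxelGrid, *, require_connected: bool = True) -> VoxelGraph:
    """26-connectivity graph over occupied voxels with Euclidean weights."""
    nodes = grid.occupied_indices()
    if len(nodes) == 0:
        raise ValueError("cannot build a graph over an empty grid")
    n = len(nodes)
    ids = -np.ones(grid.shape, dtype=np.int64)
    ids[tuple(nodes.T)] = np.arange(n)
    rows, cols, weights = [], [], []
    shape = np.array(grid.shape)
    for off in _HALF_OFFSETS:
        shifted = nodes + off
        valid = np.all((shifted >= 0) & (shifted < shape), axis=1)
        src = np.nonzero(valid)[0]
        dst = ids[tuple(shifted[valid].T)]
        hit = dst >= 0
        src, dst = src[hit], dst[hit]
        if len(src) == 0:
            continue
        w = grid.h * float(np.linalg.norm(off))
        rows.append(src)
        cols.append(dst)
        weights.append(np.full(len(src), w))
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        w = np.concatenate(weights)
        adj = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([r, c]), np.concatenate([c, r]))),
            shape=(n, n),
        ).tocsr()
    else:
        adj = csr_matrix((n, n))
    if require_connected and n > 1:
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp > 1:
            raise ValueError(
                f"occupied voxels form {n_comp} components; "
                "filter to the largest component before building the graph"
            )
    return VoxelGraph(nodes=nodes, adjacency=adj, h=grid.h, grid=grid)


def surface_subgraph(surface: SurfaceVoxels) -> VoxelGraph:
    """26-connectivity graph restricted to the surface voxels only.

    Used by the geodesic-distance baseline; unlike the full volume graph
    it may be disconnected, which callers must handle.
    """
    sub = VoxelGrid(
        origin=surface.grid.origin,
        h=surface.grid.h,
        occupancy=np.zeros(surface.grid.shape, dtype=bool),
        source_id=surface.grid.source_id,
    )
    sub.occupancy[tuple(surface.indices.T)] = True
    return build_voxel_graph(sub, require_connected=False)


def lloyd_sample(
    surface: SurfaceVoxels,
    n: int,
    seed: int = 0,
    max_iter: int = 20,
) -> SamplePoints:
    """Spread ``n`` landmarks over the surface voxels by Lloyd relaxation.

    k-means-style: assign every surface voxel to its nearest site by
    Euclidean distance, move each site to the surface voxel nearest its
    cluster centroid, stop when no site moves or after ``max_iter``
    rounds.  Deterministic for a fixed seed.
    """
    m = len(surface)
    if n < 1:
        raise ValueError("need n >= 1 sample points")
    if n > m:
        raise ValueError(f"cannot sample {n} points from {m} surface voxels")
    pts = surface.indices.astype(float)
    rng = np.random.default_rng(seed)
    site_ids = rng.choice(m, size=n, replace=False)
    if n == m:
        return SamplePoints(indices=surface.indices.copy(), grid=surface.grid, seed=seed)
    tree_all = cKDTree(pts)
    for _ in range(max_iter):
        sites = pts[site_ids]
        _, assign = cKDTree(sites).query(pts)
        new_ids = site_ids.copy()
        for j in range(n):
            members = pts[assign == j]
            if len(members) == 0:
                continue  # empty cluster keeps its site
            centroid = members.mean(axis=0)
            _, nearest = tree_all.query(centroid)
            new_ids[j] = nearest
        # Resolve collisions so sites stay pairwise distinct.
        seen: set[int] = set()
        for j in range(n):
            if int(new_ids[j]) in seen:
                new_ids[j] = site_ids[j]
            if int(new_ids[j]) in seen:
                free = np.setdiff1d(np.arange(m), np.fromiter(seen, dtype=int))
                d = np.linalg.norm(pts[free] - pts[new_ids[j]], axis=1)
                new_ids[j] = free[int(np.argmin(d))]
            seen.add(int(new_ids[j]))
        if np.array_equal(np.sort(new_ids), np.sort(site_ids)):
            site_ids = new_ids
            break
        site_ids = new_ids
    return SamplePoints(
        indices=surface.indices[np.sort(site_ids)], grid=surface.grid, seed=seed
    )


def inner_distance(graph: VoxelGraph, p, q) -> float:
    """Shortest-path length (Angstrom) between two voxels through the volume."""
    i, j = graph.node_id(p), graph.node_id(q)
    if i == j:
        return 0.0
    dist = dijkstra(graph.adjacency, directed=False, indices=[i])[0]
    d = float(dist[j])
    if not np.isfinite(d):
        raise ValueError(f"voxels {tuple(p)} and {tuple(q)} are not connected")
    return d


def all_pairs_inner_distances(
    graph: VoxelGraph, samples: SamplePoints
) -> InnerDistanceSet:
    """All n(n-1)/2 pairwise inner distances over the landmark set.

    One single-source Dijkstra sweep per landmark over the sparse voxel
    graph.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need >=2 sample points for pairwise distances")
    idx = np.array([graph.node_id(v) for v in samples.indices])
    dist = dijkstra(graph.adjacency, directed=False, indices=idx)
    sub = dist[:, idx]
    iu = np.triu_indices(n, k=1)
    values = sub[iu]
    if not np.all(np.isfinite(values)):
        raise ValueError("some landmark pairs are disconnected")
    return InnerDistanceSet(
        values=values, n_points=n, source_id=samples.grid.source_id
    )


def pairwise_euclidean(samples: SamplePoints) -> InnerDistanceSet:
    """Condensed Euclidean (chord) distances over the same landmark set."""
    from scipy.spatial.distance import pdist

    n = len(samples)
    if n < 2:
        raise ValueError("need >=2 sample points for pairwise distances")
    return InnerDistanceSet(
        values=pdist(samples.centers()), n_points=n,
        source_id=samples.grid.source_id,
    )
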