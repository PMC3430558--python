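"""Synthetic rigid and articulated test solids.

Generates voxelized capsules (rods), bent capsules articulated at the
midpoint, spheres and dumbbells.  These emulate the conformer families of
flexible-molecule benchmarks: a bent rod is the same tube as the straight
rod, articulated by a hinge, so its volume and its through-volume path
lengths are preserved while chord (Euclidean) distances shrink — exactly
the contrast a deformation-invariant signature must resolve.

All generators are deterministic for a fixed ``(kind, params, seed)``;
the seed draws a random 3D orientation so that repeated conformers are
not lattice-aligned copies of each other.  ``seed=None`` keeps the
canonical axis-aligned pose.
"""

from __future__ import annotations

import math

import numpy as np

from .molio import VoxelGrid, largest_component


def _random_rotation(seed: int | None) -> np.ndarray:
    """Uniform random rotation matrix (identity for ``seed=None``)."""
    if seed is None:
        return np.eye(3)
    rng = np.random.default_rng(seed)
    # QR of a Gaussian matrix with sign fix gives a Haar-uniform rotation.
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _voxelize_distance_field(
    dist_fn, extent: float, h: float, source_id: str
) -> VoxelGrid:
    """Voxelize ``{x : dist_fn(x) <= 0}`` over a centered cube of half-width
    ``extent``."""
    n = int(math.ceil(2 * extent / h)) + 1
    axis = (np.arange(n) - (n - 1) / 2) * h
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    occ = (dist_fn(pts) <= 0).reshape(n, n, n)
    if not occ.any():
        raise ValueError("degenerate parameters produced an empty shape")
    occ = largest_component(occ)
    origin = np.full(3, -(n - 1) / 2 * h)
    return VoxelGrid(origin=origin, h=h, occupancy=occ, source_id=source_id)


def make_synthetic_shape(
    kind: str,
    *,
    length: float | None = None,
    radius: float | None = None,
    bend_angle: float = 0.0,
    radius2: float | None = None,
    neck_radius: float | None = None,
    h: float = 1.0,
    seed: int | None = None,
    source_id: str = "",
) -> VoxelGrid:
    """Generate a voxelized synthetic solid.

    Parameters
    ----------
    kind
        One of ``rod``, ``bent_rod``, ``sphere``, ``dumbbell``.
    length, radius
        Tube axis length and tube radius for rods (Angstrom-equivalent
        lattice units); sphere radius for ``sphere``; for ``dumbbell``,
        ``radius``/``radius2`` are the two lobe radii and ``length`` the
        center-to-center separation.
    bend_angle
        Articulation angle in degrees for ``bent_rod`` (0 reproduces the
        straight rod): the tube is hinged at its midpoint, each arm
        deflected symmetrically so the arms enclose ``180 - bend_angle``
        degrees.
    neck_radius
        Connecting-cylinder radius for ``dumbbell``.
    seed
        Draws a random rigid orientation; ``None`` keeps the canonical
        axis-aligned pose.  Deterministic for a fixed value.
    """
    if h <= 0:
        raise ValueError("lattice spacing h must be positive")
    rot = _random_rotation(seed)
    sid = source_id or f"{kind}-{seed}"

    if kind == "rod" or kind == "bent_rod":
        if length is None or radius is None or length <= 0 or radius <= 0:
            raise ValueError("rod needs positive length and radius")
        angle = math.radians(bend_angle if kind == "bent_rod" else 0.0)
        half = length / 2.0
        # Hinge at the origin; each arm deflected by angle/2 off the x axis.
        d1 = np.array([math.cos(angle / 2), math.sin(angle / 2), 0.0])
        d2 = np.array([-math.cos(angle / 2), math.sin(angle / 2), 0.0])
        a1, a2 = half * d1, half * d2
        origin3 = np.zeros(3)

        def dist_fn(pts: np.ndarray) -> np.ndarray:
            local = pts @ rot  # rotate the shape by `rot`: evaluate at R^T x
            d_arm1 = _segment_distance(local, origin3, a1)
            d_arm2 = _segment_distance(local, origin3, a2)
            return np.minimum(d_arm1, d_arm2) - radius

        extent = half + radius + h
        return _voxelize_distance_field(dist_fn, extent, h, sid)

    if kind == "sphere":
        if radius is None or radius <= 0:
            raise ValueError("sphere needs a positive radius")

        def dist_fn(pts: np.ndarray) -> np.ndarray:
            return np.linalg.norm(pts, axis=1) - radius

        return _voxelize_distance_field(dist_fn, radius + h, h, sid)

    if kind == "dumbbell":
        r1 = radius
        r2 = radius2 if radius2 is not None else radius
        if r1 is None or r1 <= 0 or r2 is None or r2 <= 0:
            raise ValueError("dumbbell needs positive lobe radii")
        sep = length if length is not None else 2.0 * (r1 + r2)
        if sep <= 0:
            raise ValueError("dumbbell needs a positive lobe separation")
        rn = neck_radius if neck_radius is not None else 0.4 * min(r1, r2)
        if rn <= 0:
            raise ValueError("dumbbell needs a positive neck radius")
        c1 = np.array([-sep / 2, 0.0, 0.0])
        c2 = np.array([sep / 2, 0.0, 0.0])

        def dist_fn(pts: np.ndarray) -> np.ndarray:
            d1 = np.linalg.norm(pts - c1, axis=1) - r1
            d2 = np.linalg.norm(pts - c2, axis=1) - r2
            dn = _segment_distance(pts, c1, c2) - rn
            return np.minimum(np.minimum(d1, d2), dn)

        def rotated(pts: np.ndarray) -> np.ndarray:
            return dist_fn(pts @ rot)

        extent = sep / 2 + max(r1, r2) + h
        return _voxelize_distance_field(rotated, extent, h, sid)

    raise ValueError(f"unknown synthetic shape kind {kind!r}")


def benchmark_database(
    seed: int = 0,
    *,
    n_conformers: int = 5,
    max_bend: float = 90.0,
    h: float = 1.0,
) -> list[tuple[str, str, VoxelGrid]]:
    """Synthetic retrieval benchmark: articulated families plus distractors.

    Four tube families with distinct aspect ratios, each articulated into
    ``n_conformers`` bend angles evenly spaced over ``[0, max_bend]``
    degrees and given an independent random orientation — a stand-in for
    conformer groups of flexible molecules.  Ten rigid distractors
    (spheres and dumbbells of varied proportions) are appended as
    singleton groups.

    Returns ``(molecule id, group label, grid)`` triples.
    """
    # All families share one tube radius and differ only in length, so
    # family identity is a purely global property: local curvature
    # carries no family signal and articulation confounds chord lengths.
    families = {
        "tube_len48": dict(length=48.0, radius=3.0),
        "tube_len34": dict(length=34.0, radius=3.0),
        "tube_len24": dict(length=24.0, radius=3.0),
        "tube_len17": dict(length=17.0, radius=3.0),
    }
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, VoxelGrid]] = []
    angles = np.linspace(0.0, max_bend, n_conformers)
    for group, params in families.items():
        for i, angle in enumerate(angles):
            conformer_seed = int(rng.integers(1, 2**31 - 1))
            mol_id = f"{group}_c{i}"
            grid = make_synthetic_shape(
                "bent_rod",
                bend_angle=float(angle),
                h=h,
                seed=conformer_seed,
                source_id=mol_id,
                **params,
            )
            records.append((mol_id, group, grid))
    sphere_radii = [5.0, 7.0, 9.0, 11.0, 13.0]
    for i, r in enumerate(sphere_radii):
        mol_id = f"distractor_sphere{i}"
        grid = make_synthetic_shape(
            "sphere", radius=r, h=h,
            seed=int(rng.integers(1, 2**31 - 1)), source_id=mol_id,
        )
        records.append((mol_id, mol_id, grid))
    dumbbell_params = [
        dict(radius=5.0, radius2=5.0, length=18.0, neck_radius=2.0),
        dict(radius=7.0, radius2=4.0, length=20.0, neck_radius=2.5),
        dict(radius=6.0, radius2=6.0, length=26.0, neck_radius=3.0),
        dict(radius=8.0, radius2=5.0, length=24.0, neck_radius=2.0),
        dict(radius=4.0, radius2=4.0, length=14.0, neck_radius=1.5),
    ]
    for i, params in enumerate(dumbbell_params):
        mol_id = f"distractor_dumbbell{i}"
        grid = make_synthetic_shape(
            "dumbbell", h=h,
            seed=int(rng.integers(1, 2**31 - 1)), source_id=mol_id, **params,
        )
        records.append((mol_id, mol_id, grid))
    return records
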