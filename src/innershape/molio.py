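"""Molecular input and volumetric modelling.

Reads one chain of a PDB file into an atom set, converts it into a
solvent-excluded volume on a uniform cubic lattice (the voxelized
approximation of the Connolly surface), and extracts the boundary voxels
that downstream sampling operates on.

The solvent-excluded volume is approximated by a morphological closing of
the van der Waals union on the lattice: every voxel whose center lies
within ``radius + probe`` of an atom is marked, then the marked set is
eroded by the probe radius using a Euclidean distance transform.  The
approximation converges to the analytic surface as the lattice spacing
``h`` goes to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (Angstrom) for the elements that dominate
#: macromolecules; anything else falls back to carbon.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

#: Largest lattice dimension allowed before the spacing is rescaled.
DEFAULT_DIM_CAP = 96

_FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


class ChainNotFoundError(KeyError):
    """Requested chain identifier does not exist in the structure."""


class EmptyStructureError(ValueError):
    """No atoms remain after filtering (e.g. waters-only input)."""


@dataclass(frozen=True)
class AtomSet:
    """Atoms of one chain: element symbols, coordinates and vdW radii."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float, Angstrom
    radii: np.ndarray  # (n,) float, Angstrom
    chain_id: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise EmptyStructureError("atom set needs >=1 atom with xyz coordinates")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinates")
        if radii.shape != (coords.shape[0],) or np.any(radii <= 0):
            raise ValueError("every atom needs a positive vdW radius")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class VoxelGrid:
    """Boolean occupancy on a uniform cubic lattice.

    ``origin`` is the world-space position of voxel index (0, 0, 0)'s
    center; ``h`` is the lattice spacing in Angstrom.
    """

    origin: np.ndarray
    h: float
    occupancy: np.ndarray  # boolean (nx, ny, nz)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.h <= 0:
            raise ValueError("lattice spacing h must be positive")
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def occupied_indices(self) -> np.ndarray:
        """Lattice coordinates of occupied voxels, shape (n, 3)."""
        return np.argwhere(self.occupancy)

    def centers(self, indices: np.ndarray) -> np.ndarray:
        """World-space centers (Angstrom) of the given lattice indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.h

    def volume(self) -> float:
        """Occupied volume in cubic Angstrom."""
        return self.n_occupied * self.h**3


@dataclass
class SurfaceVoxels:
    """Occupied voxels with at least one unoccupied 6-neighbor."""

    indices: np.ndarray  # (n, 3) int lattice coordinates
    grid: VoxelGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.indices)

    def centers(self) -> np.ndarray:
        return self.grid.centers(self.indices)


def vdw_radius(element: str) -> float:
    """vdW radius for an element symbol; unknown elements get carbon's."""
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)


def read_structure(
    path: str,
    chain: str,
    *,
    include_hetatm: bool = False,
    source_id: str | None = None,
) -> AtomSet:
    """Read one chain of a PDB file into an :class:`AtomSet`.

    Waters are always excluded; HETATM records are excluded unless
    ``include_hetatm`` is set.  Only the first model of multi-model files
    is used.

    Raises
    ------
    ChainNotFoundError
        If the chain identifier is absent from the first model.
    EmptyStructureError
        If no atoms survive filtering.
    """
    import gemmi

    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = structure[0]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        available = ", ".join(ch.name for ch in model) or "<none>"
        raise ChainNotFoundError(
            f"chain {chain!r} not found in {path} (available: {available})"
        )
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for residue in chain_obj:
        if residue.is_water():
            continue
        het = residue.het_flag == "H"
        if het and not include_hetatm:
            continue
        for atom in residue:
            elements.append(atom.element.name)
            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not coords:
        raise EmptyStructureError(
            f"no atoms left in chain {chain!r} of {path} after filtering"
        )
    radii = np.array([vdw_radius(e) for e in elements])
    if source_id is None:
        stem = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
        source_id = f"{stem}-{chain}"
    return AtomSet(
        elements=tuple(elements),
        coords=np.asarray(coords, dtype=float),
        radii=radii,
        chain_id=chain,
        source_id=source_id,
    )


def _paint_spheres(
    occupancy: np.ndarray,
    origin: np.ndarray,
    h: float,
    coords: np.ndarray,
    radii: np.ndarray,
) -> None:
    """Mark voxels whose centers lie within each sphere (in place)."""
    shape = occupancy.shape
    for center, radius in zip(coords, radii):
        idx_center = (center - origin) / h
        r_vox = radius / h
        lo = np.maximum(np.ceil(idx_center - r_vox).astype(int), 0)
        hi = np.minimum(np.floor(idx_center + r_vox).astype(int), np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        dx = (ax[0] - idx_center[0]) ** 2
        dy = (ax[1] - idx_center[1]) ** 2
        dz = (ax[2] - idx_center[2]) ** 2
        inside = (
            dx[:, None, None] + dy[None, :, None] + dz[None, None, :]
        ) <= r_vox**2
        occupancy[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside
    return None


def largest_component(occupancy: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean lattice."""
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(occupancy, structure=structure)
    if n <= 1:
        return occupancy
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def voxelize(
    atoms: AtomSet,
    h: float = 1.0,
    probe: float = 1.4,
    *,
    dim_cap: int = DEFAULT_DIM_CAP,
) -> VoxelGrid:
    """Voxelize an atom set into its approximate solvent-excluded volume.

    Marks voxels within ``radius + probe`` of any atom, erodes the marked
    set by ``probe`` via a Euclidean distance transform (a morphological
    closing of the vdW union), and keeps the largest 26-connected
    component.  If the lattice would exceed ``dim_cap`` along any axis,
    ``h`` is scaled up automatically and a warning is logged.
    """
    if h <= 0:
        raise ValueError("lattice spacing h must be positive")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    pad = float(np.max(atoms.radii)) + probe + h
    lo = atoms.coords.min(axis=0) - pad
    hi = atoms.coords.max(axis=0) + pad
    # Snap the origin to an absolute lattice so that translating the atoms
    # by integer multiples of h shifts occupancy without re-discretization.
    h_in = h
    while True:
        origin = np.floor(lo / h) * h
        shape = tuple(np.ceil((hi - origin) / h).astype(int) + 1)
        if max(shape) <= dim_cap:
            break
        h *= max(shape) / dim_cap
    if h != h_in:
        logger.warning(
            "lattice for %s exceeds %d^3 at h=%.3g A; rescaled to h=%.3g A",
            atoms.source_id or "<atoms>", dim_cap, h_in, h,
        )

    dilated = np.zeros(shape, dtype=bool)
    _paint_spheres(dilated, origin, h, atoms.coords, atoms.radii + probe)
    if probe > 0:
        # Erode by the probe: keep voxels farther than `probe` from the
        # complement of the dilated set.
        dist = ndimage.distance_transform_edt(dilated, sampling=h)
        closed = dist >= probe
        # Closing never removes the vdW union itself; enforce on-lattice.
        vdw = np.zeros(shape, dtype=bool)
        _paint_spheres(vdw, origin, h, atoms.coords, atoms.radii)
        closed |= vdw
    else:
        closed = dilated
    if not closed.any():
        raise ValueError("voxelization produced an empty grid")
    closed = largest_component(closed)
    return VoxelGrid(origin=origin, h=h, occupancy=closed, source_id=atoms.source_id)


def extract_surface(grid: VoxelGrid) -> SurfaceVoxels:
    """Occupied voxels with >=1 unoccupied 6-neighbor (grid edge counts)."""
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("cannot extract the surface of an empty grid")
    padded = np.pad(occ, 1, constant_values=False)
    interior = padded[1:-1, 1:-1, 1:-1].copy()
    for off in _FACE_OFFSETS:
        sl = tuple(slice(1 + o, s + 1 + o) for o, s in zip(off, occ.shape))
        interior &= padded[sl]
    surface = occ & ~interior
    return SurfaceVoxels(indices=np.argwhere(surface), grid=grid)


# ---------------------------------------------------------------------------
# Grid container format: a small self-describing text format with a header
# (origin / spacing / shape) and hex-packed occupancy bits, plus a
# plain-text voxel list export for interoperability.
# ---------------------------------------------------------------------------

_VOX_MAGIC = "innershape-vox 1"


def save_grid(grid: VoxelGrid, path: str) -> None:
    """Write a grid to the package's text container format."""
    bits = np.packbits(grid.occupancy.ravel().astype(np.uint8))
    with open(path, "w") as fh:
        fh.write(f"{_VOX_MAGIC}\n")
        fh.write(f"id {grid.source_id}\n")
        fh.write("origin {:.9g} {:.9g} {:.9g}\n".format(*grid.origin))
        fh.write(f"h {grid.h:.9g}\n")
        fh.write("shape {} {} {}\n".format(*grid.shape))
        hexdata = bits.tobytes().hex()
        for i in range(0, len(hexdata), 120):
            fh.write(hexdata[i : i + 120] + "\n")


def load_grid(path: str) -> VoxelGrid:
    """Read a grid written by :func:`save_grid`."""
    with open(path) as fh:
        if fh.readline().strip() != _VOX_MAGIC:
            raise ValueError(f"{path} is not an innershape grid file")
        source_id = fh.readline().split(" ", 1)[1].strip()
        origin = np.array(fh.readline().split()[1:4], dtype=float)
        h = float(fh.readline().split()[1])
        shape = tuple(int(x) for x in fh.readline().split()[1:4])
        hexdata = "".join(line.strip() for line in fh)
    bits = np.frombuffer(bytes.fromhex(hexdata), dtype=np.uint8)
    n = int(np.prod(shape))
    occupancy = np.unpackbits(bits)[:n].reshape(shape).astype(bool)
    return VoxelGrid(origin=origin, h=h, occupancy=occupancy, source_id=source_id)


def export_voxel_list(grid: VoxelGrid, path: str) -> None:
    """Write occupied lattice coordinates as whitespace-separated triples."""
    np.savetxt(path, grid.occupied_indices(), fmt="%d", header="i j k")
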