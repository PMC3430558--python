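"""Shared fixtures: tiny PDB files written on the fly and reusable
synthetic grids/descriptors (session-scoped, they are moderately
expensive)."""

from __future__ import annotations

import numpy as np
import pytest

import innershape as ins


def format_pdb_atom(serial, name, resname, chain, resseq, x, y, z, element,
                    record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:<4} {resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three-atom chain A (C, N, O backbone-ish fragment)."""
    lines = [
        format_pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        format_pdb_atom(2, "N", "ALA", "A", 1, 1.5, 0.0, 0.0, "N"),
        format_pdb_atom(3, "O", "ALA", "A", 1, 0.0, 1.5, 0.0, "O"),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def water_only_pdb(tmp_path):
    lines = [
        format_pdb_atom(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, "O",
                        record="HETATM"),
        format_pdb_atom(2, "O", "HOH", "A", 2, 3.0, 0.0, 0.0, "O",
                        record="HETATM"),
        "END",
    ]
    path = tmp_path / "water.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def block_grid(shape, h=1.0):
    """Fully occupied rectangular block as a VoxelGrid."""
    return ins.VoxelGrid(
        origin=np.zeros(3), h=h, occupancy=np.ones(shape, dtype=bool),
        source_id="block",
    )


@pytest.fixture(scope="session")
def rod_grid():
    return ins.make_synthetic_shape("rod", length=40, radius=3,
                                    source_id="rod")


@pytest.fixture(scope="session")
def bent60_grid():
    return ins.make_synthetic_shape("bent_rod", length=40, radius=3,
                                    bend_angle=60, source_id="bent60")


@pytest.fixture(scope="session")
def sphere_grid():
    """Ball volume-matched to the L=40, r=3 capsule (r ~= 6.7)."""
    return ins.make_synthetic_shape("sphere", radius=6.7, source_id="sphere")


@pytest.fixture(scope="session")
def sphere8_grid():
    return ins.make_synthetic_shape("sphere", radius=8.0, source_id="sphere8")


@pytest.fixture(scope="session")
def rod_idss(rod_grid):
    return ins.describe(rod_grid, "IDSS", n_samples=128, seed=1)


@pytest.fixture(scope="session")
def bent60_idss(bent60_grid):
    return ins.describe(bent60_grid, "IDSS", n_samples=128, seed=1)


@pytest.fixture(scope="session")
def sphere_idss(sphere_grid):
    return ins.describe(sphere_grid, "IDSS", n_samples=128, seed=1)


@pytest.fixture(scope="session")
def rod_d2(rod_grid):
    return ins.describe(rod_grid, "D2", n_samples=128, seed=1)


@pytest.fixture(scope="session")
def bent60_d2(bent60_grid):
    return ins.describe(bent60_grid, "D2", n_samples=128, seed=1)


@pytest.fixture(scope="session")
def sphere_d2(sphere_grid):
    return ins.describe(sphere_grid, "D2", n_samples=128, seed=1)
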