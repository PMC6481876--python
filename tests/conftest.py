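"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import shapespace as ss
from shapespace.pipeline import RunConfig, descriptor_for_mesh
from shapespace.structure_io import AtomSet


# ---------------------------------------------------------------- oracles

def gram_schmidt_radial_coeffs(n_max: int) -> dict[tuple[int, int], np.ndarray]:
    """Radial polynomial coefficients derived independently of the production
    path: for each l, orthonormalize the monomials r^l, r^(l+2), ... with
    respect to r^2 dr on [0, 1] via Cholesky of the exact Gram matrix
    G_ab = 1/(2l + 2a + 2b + 3).  Returns, per (n, l), the coefficients of
    r^(l+2a); signs fixed so the value at r = 1 is positive.
    """
    out = {}
    for l in range(n_max + 1):
        k_max = (n_max - l) // 2
        a = np.arange(k_max + 1)
        gram = 1.0 / (2 * l + 2 * a[:, None] + 2 * a[None, :] + 3)
        chol = np.linalg.cholesky(gram)
        coeffs = np.linalg.inv(chol)          # rows: orthonormal combinations
        for i in range(k_max + 1):
            row = coeffs[i].copy()
            if row.sum() < 0:
                row = -row
            out[(l + 2 * i, l)] = row
    return out


def oracle_radial(n: int, l: int, r: np.ndarray,
                  coeffs: dict | None = None) -> np.ndarray:
    if coeffs is None:
        coeffs = gram_schmidt_radial_coeffs(n)
    row = coeffs[(n, l)]
    powers = l + 2 * np.arange(len(row))
    return sum(c * r**p for c, p in zip(row, powers))


def oracle_moments(points: np.ndarray, weights: np.ndarray, n_max: int):
    """Zernike moments by direct quadrature with an independently constructed
    basis (Gram-Schmidt radial polynomials x scipy spherical harmonics)."""
    from scipy.special import sph_harm_y

    coeffs = gram_schmidt_radial_coeffs(n_max)
    r = np.linalg.norm(points, axis=1)
    safe = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(points[:, 2] / safe, -1, 1))
    phi = np.arctan2(points[:, 1], points[:, 0])
    norm = 3.0 / (4.0 * np.pi)
    omega = {}
    for l in range(n_max + 1):
        for n in range(l, n_max + 1, 2):
            rad = oracle_radial(n, l, r, coeffs)
            row = np.zeros(2 * l + 1, dtype=complex)
            for m in range(-l, l + 1):
                y = sph_harm_y(l, m, theta, phi)
                row[m + l] = norm * np.sum(weights * rad * np.conj(y))
            omega[(n, l)] = row
    return omega


def cubic_rotations(occupancy: np.ndarray) -> list[np.ndarray]:
    """All 24 proper rotations of a cubic occupancy array."""
    out = []
    for perm in itertools.permutations(range(3)):
        pmat = np.zeros((3, 3))
        for i, p in enumerate(perm):
            pmat[i, p] = 1
        for flips in itertools.product((0, 1), repeat=3):
            if np.linalg.det(pmat) * (-1) ** sum(flips) < 0:
                continue
            arr = np.transpose(occupancy, perm)
            for axis, f in enumerate(flips):
                if f:
                    arr = np.flip(arr, axis=axis)
            out.append(arr.copy())
    assert len(out) == 24
    return out


# ---------------------------------------------------------------- fixtures

def make_atom_set(coords: np.ndarray, radius: float = 1.7,
                  chain: str = "A") -> AtomSet:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return AtomSet(
        coordinates=coords,
        elements=np.array(["C"] * n),
        radii=np.full(n, radius),
        chain_ids=np.array([chain] * n),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.array(["UNK"] * n),
    )


def helix_pdb_text(n_res: int = 12, chains=("A",), biomt: bool = False,
                   gap_after: int | None = None, gap_shift: float = 100.0) -> str:
    """Synthetic poly-alanine helix PDB text (backbone atoms only)."""
    lines = ["HEADER    SYNTHETIC FIXTURE"]
    if biomt:
        lines += [
            "REMARK 350 BIOMOLECULE: 1",
            "REMARK 350 APPLY THE FOLLOWING TO CHAINS: " + ", ".join(chains),
            "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000",
            "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000",
            "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000",
            "REMARK 350   BIOMT1   2  1.000000  0.000000  0.000000       30.00000",
            "REMARK 350   BIOMT2   2  0.000000  1.000000  0.000000        0.00000",
            "REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000",
        ]
    serial = 1
    backbone = [("N", "N", (-0.5, 0.0, -0.5)), ("CA", "C", (0.0, 0.0, 0.0)),
                ("C", "C", (0.5, 0.3, 0.2)), ("O", "O", (0.9, 0.5, 0.2))]
    for ci, ch in enumerate(chains):
        for i in range(n_res):
            t = 100.0 * i * np.pi / 180.0
            x = 2.3 * np.cos(t)
            y = 2.3 * np.sin(t) + ci * 60.0
            z = 1.5 * i
            if gap_after is not None and i >= gap_after:
                x += gap_shift
            for name, el, (dx, dy, dz) in backbone:
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s}ALA {ch}{i + 1:4d}    "
                    f"{x + dx:8.3f}{y + dy:8.3f}{z + dz:8.3f}  1.00  0.00"
                    f"          {el:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "helix.pdb"
    p.write_text(helix_pdb_text(12, ("A", "B")))
    return p


@pytest.fixture(scope="session")
def assembly_pdb(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "dimer_bu.pdb"
    p.write_text(helix_pdb_text(12, ("A",), biomt=True))
    return p


@pytest.fixture(scope="session")
def ellipsoid_specs():
    return ss.ellipsoid_series()


@pytest.fixture(scope="session")
def series_descriptors_64(ellipsoid_specs):
    """Production-path descriptors of the eccentricity series at grid 64.

    Shared by the rotation-invariance, monotonicity and map tests; the
    maximum pairwise distance serves as the series' distance spread.
    """
    cfg = RunConfig(grid_n=64)
    descs = [descriptor_for_mesh(ss.ellipsoid_mesh(s), cfg)
             for s in ellipsoid_specs]
    spread = max(ss.descriptor_distance(a, b)
                 for a, b in itertools.combinations(descs, 2))
    return {"descriptors": descs, "spread": spread, "config": cfg}


@pytest.fixture(scope="session")
def blob_grid_40():
    """Voxelized two-lobe blob surface on a small grid (asymmetric fixture)."""
    atoms = ss.blob_atoms(2, 40, seed=3)
    mesh = ss.build_surface(atoms, resolution=0.7)
    return ss.voxelize_mesh(mesh, n=40)
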