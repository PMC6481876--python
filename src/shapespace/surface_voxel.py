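"""Molecular surface construction and binary shell voxelization.

Surface: a Gaussian-density isosurface.  Each atom contributes
``exp(-beta * ((|x - x_i| / (r_i + probe))^2 - 1))`` so that an isolated
atom's unit-level isosurface sits exactly at its (probe-inflated) van der
Waals radius; the union density is contoured by marching cubes.  Surface
components that lie inside another component (buried cavities) are
discarded.

Voxelization: the mesh is centered and uniformly scaled into an N^3 grid
with a 2-voxel margin, and a voxel is set to 1 iff its center lies closer
than ``shell_thickness`` grid intervals (default 1.7) to any surface
triangle — a binary shell, with no interior fill.  The occupied shell is
what the Zernike expansion sees after mapping to the unit ball.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .synthetic_shapes import PointCloud

__all__ = [
    "VoxelGrid",
    "build_surface",
    "voxelize_mesh",
    "grid_to_unit_ball",
    "DEFAULT_GRID_N",
    "DEFAULT_SHELL_THICKNESS",
]

DEFAULT_GRID_N = 200
DEFAULT_SHELL_THICKNESS = 1.7
DEFAULT_FILL_FRACTION = 0.7
_GAUSS_SHARPNESS = 2.3          # decay rate of the atomic Gaussians
_DENSITY_CUTOFF_RHO = 2.3       # ignore atom contributions beyond this rho


@dataclass
class VoxelGrid:
    """N^3 binary occupancy grid with physical spacing and origin.

    ``origin`` is the physical position of the center of voxel (0, 0, 0);
    voxel (i, j, k) is centered at ``origin + spacing * (i, j, k)``.
    """

    occupancy: np.ndarray
    spacing: float
    origin: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3 or len(set(self.occupancy.shape)) != 1:
            raise ValueError("occupancy must be a cubic N^3 array")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def n(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


class DegenerateInputError(ValueError):
    """Raised when input geometry is degenerate (coincident/coplanar points)."""


def build_surface(atoms, probe: float = 0.0, density_level: float = 1.0,
                  resolution: float = 0.5, max_grid: int = 192) -> trimesh.Trimesh:
    """Gaussian-density isosurface of an atom set.

    Parameters
    ----------
    atoms : AtomSet
        Atoms with coordinates and van der Waals radii (Angstrom).
    probe : float
        Probe radius added to every atomic radius before blurring; 0 gives a
        van-der-Waals-like envelope, 1.4 a water-probe-inflated one.
    density_level : float
        Isosurface level; 1.0 crosses an isolated atom exactly at its
        (inflated) radius, lower values inflate the surface.
    resolution : float
        Target grid spacing in Angstrom; coarsened if the bounding box would
        exceed ``max_grid`` cells per axis.
    """
    coords = np.asarray(atoms.coordinates, dtype=float)
    radii = np.asarray(atoms.radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("atom set must contain at least one atom")
    if density_level <= 0:
        raise ValueError("density_level must be positive")
    if len(coords) > 1 and np.all(np.ptp(coords, axis=0) < 1e-9):
        raise DegenerateInputError("all atoms coincide; no surface exists")

    reach = (radii + probe) * _DENSITY_CUTOFF_RHO
    lo = (coords - reach[:, None]).min(axis=0) - 2 * resolution
    hi = (coords + reach[:, None]).max(axis=0) + 2 * resolution
    extent = hi - lo
    h = max(resolution, float(extent.max()) / max_grid)
    dims = np.maximum(np.ceil(extent / h).astype(int) + 1, 4)

    density = np.zeros(dims)
    inv_r2 = 1.0 / (radii + probe) ** 2
    for xyz, inv, rch in zip(coords, inv_r2, reach):
        alo = np.maximum(np.floor((xyz - rch - lo) / h).astype(int), 0)
        ahi = np.minimum(np.ceil((xyz + rch - lo) / h).astype(int) + 1, dims)
        gx = lo[0] + h * np.arange(alo[0], ahi[0])
        gy = lo[1] + h * np.arange(alo[1], ahi[1])
        gz = lo[2] + h * np.arange(alo[2], ahi[2])
        d2 = ((gx - xyz[0]) ** 2)[:, None, None] \
            + ((gy - xyz[1]) ** 2)[None, :, None] \
            + ((gz - xyz[2]) ** 2)[None, None, :]
        density[alo[0]:ahi[0], alo[1]:ahi[1], alo[2]:ahi[2]] += np.exp(
            -_GAUSS_SHARPNESS * (d2 * inv - 1.0))

    if density.max() <= density_level:
        raise ValueError("no surface at the requested density level")
    verts, faces, _, _ = marching_cubes(density, level=density_level,
                                        spacing=(h, h, h))
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=True)
    mesh.fix_normals()
    return _drop_buried_components(mesh)


def _drop_buried_components(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Remove surface components enclosed by another component (cavities)."""
    comps = mesh.split(only_watertight=False)
    if len(comps) <= 1:
        return mesh
    keep = []
    for i, comp in enumerate(comps):
        buried = False
        probe_pt = comp.vertices[:1]
        for j, other in enumerate(comps):
            if i == j:
                continue
            try:
                if other.contains(probe_pt)[0]:
                    buried = True
                    break
            except Exception:  # non-watertight component: cannot enclose
                continue
        if not buried:
            keep.append(comp)
    out = trimesh.util.concatenate(keep) if keep else mesh
    out.fix_normals()
    return out


def _point_triangle_dist2(p, a, b, c):
    """Squared distance from points ``p`` to triangles ``(a, b, c)``, rowwise."""
    ab, ac, ap = b - a, c - a, p - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    safe = denom > 1e-12
    inv = np.where(safe, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / inv
    w = (d00 * d21 - d01 * d20) / inv
    inside = safe & (v >= 0) & (w >= 0) & (v + w <= 1)

    normal = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", normal, normal)
    plane = np.einsum("ij,ij->i", ap, normal) ** 2 / np.where(nn > 0, nn, 1.0)

    def seg2(q, x, y):
        xy = y - x
        denom_s = np.einsum("ij,ij->i", xy, xy)
        t = np.clip(np.einsum("ij,ij->i", q - x, xy)
                    / np.where(denom_s > 0, denom_s, 1.0), 0.0, 1.0)
        diff = q - x - t[:, None] * xy
        return np.einsum("ij,ij->i", diff, diff)

    edge = np.minimum(np.minimum(seg2(p, a, b), seg2(p, b, c)), seg2(p, c, a))
    return np.where(inside, plane, edge)


def voxelize_mesh(mesh: trimesh.Trimesh, n: int = DEFAULT_GRID_N,
                  shell_thickness: float = DEFAULT_SHELL_THICKNESS,
                  margin: int = 2, extent: float | None = None) -> VoxelGrid:
    """Binary surface-shell voxelization of a triangle mesh.

    The mesh bounding box is centered in the grid and uniformly scaled so its
    largest extent spans ``n - 2 * margin`` voxels; a voxel is occupied iff
    its center is within ``shell_thickness`` grid intervals of a triangle
    (exact point-to-triangle distances).

    ``extent`` overrides the physical span (Angstrom) mapped onto the usable
    grid width, so several meshes can share one scale (cohort-common frame);
    by default each mesh is fitted individually.
    """
    if mesh is None or len(getattr(mesh, "faces", [])) == 0:
        raise ValueError("mesh is empty")
    if n < 8:
        raise ValueError("grid size n must be at least 8")
    verts = np.asarray(mesh.vertices, dtype=float)
    bbmin, bbmax = verts.min(axis=0), verts.max(axis=0)
    if extent is None:
        extent = float((bbmax - bbmin).max())
    if extent <= 0 or float((bbmax - bbmin).max()) <= 0:
        raise ValueError("mesh has zero extent")
    scale = (n - 2.0 * margin) / extent          # voxels per Angstrom
    center = (bbmin + bbmax) / 2.0
    grid_verts = (verts - center) * scale + n / 2.0
    tri = grid_verts[np.asarray(mesh.faces)]      # (F, 3, 3) in grid coords
    thr = float(shell_thickness)

    # per-triangle voxel-index AABB: voxel centers at i + 0.5
    lo_idx = np.clip(np.floor(tri.min(axis=1) - thr - 0.5).astype(int), 0, n - 1)
    hi_idx = np.clip(np.ceil(tri.max(axis=1) + thr - 0.5).astype(int), 0, n - 1)
    dims = np.maximum(hi_idx - lo_idx + 1, 0)
    counts = dims.prod(axis=1)

    occ = np.zeros((n, n, n), dtype=bool)
    thr2 = thr * thr
    chunk_target = 2_000_000
    start = 0
    n_faces = len(tri)
    while start < n_faces:
        stop = start
        total = 0
        while stop < n_faces and (total == 0 or total + counts[stop] <= chunk_target):
            total += counts[stop]
            stop += 1
        sel = np.arange(start, stop)
        sel = sel[counts[sel] > 0]
        start = stop
        if len(sel) == 0:
            continue
        csel = counts[sel]
        tids = np.repeat(np.arange(len(sel)), csel)
        offsets = np.arange(csel.sum()) - np.repeat(
            np.concatenate([[0], np.cumsum(csel)[:-1]]), csel)
        d = dims[sel]
        dz = offsets % d[tids, 2]
        rest = offsets // d[tids, 2]
        dy = rest % d[tids, 1]
        dx = rest // d[tids, 1]
        ii = lo_idx[sel][tids, 0] + dx
        jj = lo_idx[sel][tids, 1] + dy
        kk = lo_idx[sel][tids, 2] + dz
        pts = np.column_stack([ii, jj, kk]).astype(float) + 0.5
        t = tri[sel][tids]
        d2 = _point_triangle_dist2(pts, t[:, 0], t[:, 1], t[:, 2])
        hit = d2 < thr2
        occ[ii[hit], jj[hit], kk[hit]] = True

    spacing = 1.0 / scale
    origin = center + (0.5 - n / 2.0) * spacing
    grid = VoxelGrid(occupancy=occ, spacing=spacing, origin=origin)
    if occ.all():
        warnings.warn("voxel grid is saturated: grid too small to resolve mesh")
        grid.saturated = True
    return grid


def grid_to_unit_ball(grid: VoxelGrid,
                      fill_fraction: float = DEFAULT_FILL_FRACTION,
                      reference_radius: float | None = None) -> PointCloud:
    """Map occupied voxel centers into the unit ball with uniform weights.

    Centers are translated to their centroid and uniformly scaled so the
    farthest point sits at radius ``fill_fraction``; relative geometry is
    preserved, and the result is invariant to integer grid translations.

    ``reference_radius`` (in voxel units, measured from the occupied
    centroid) overrides the per-shape maximum radius as the scale reference,
    so a cohort of grids sharing one spacing can be mapped at a common
    scale; it must be at least the shape's own maximum radius.
    """
    if not (0.0 < fill_fraction <= 1.0):
        raise ValueError("fill_fraction must lie in (0, 1]")
    idx = np.argwhere(grid.occupancy).astype(float)
    if len(idx) == 0:
        raise ValueError("voxel grid has no occupied voxels")
    pts = idx - idx.mean(axis=0)
    rmax = np.linalg.norm(pts, axis=1).max()
    if reference_radius is not None:
        if reference_radius < rmax - 1e-9:
            raise ValueError("reference_radius smaller than the shape itself")
        rmax = float(reference_radius)
    if rmax > 0:
        pts *= fill_fraction / rmax
    weights = np.full(len(pts), 1.0 / len(pts))
    return PointCloud(points=pts, correspondence_key=None, weights=weights)
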