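"""Synthetic geometry generators used to exercise and validate the pipeline.

Everything the test-bed needs is generated in code: prolate ellipsoid point
clouds sampled on a spherical-coordinate grid (with an eccentricity sweep),
watertight sphere/cube/torus meshes, and random multi-lobe pseudo-protein
atom clouds.  No external data is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "EllipsoidSpec",
    "PointCloud",
    "ellipsoid_points",
    "ellipsoid_mesh",
    "ellipsoid_series",
    "torus_mesh",
    "sphere_mesh",
    "cube_mesh",
    "blob_atoms",
    "PSEUDO_ATOM_RADIUS",
]

# fixed van der Waals radius for pseudo-atoms (carbon-like), Angstrom
PSEUDO_ATOM_RADIUS = 1.7


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid with semi-axes a >= b >= c > 0 and a theta x phi
    spherical sampling grid."""

    a: float
    b: float
    c: float
    n_theta: int = 50
    n_phi: int = 50

    def __post_init__(self) -> None:
        if not (self.a >= self.b >= self.c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got "
                             f"({self.a}, {self.b}, {self.c})")
        if self.n_theta < 2 or self.n_phi < 3:
            raise ValueError("sampling grid too coarse")

    @property
    def n_points(self) -> int:
        return self.n_theta * self.n_phi

    def eccentricity(self) -> float:
        """sqrt((2 - b^2/a^2 - c^2/a^2)/2); 0 for a sphere, -> 1 when elongated."""
        val = (2.0 - self.b**2 / self.a**2 - self.c**2 / self.a**2) / 2.0
        return float(np.sqrt(np.clip(val, 0.0, 1.0)))


@dataclass
class PointCloud:
    """Ordered 3D point set; ordering is the point correspondence contract."""

    points: np.ndarray
    correspondence_key: str | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.points),):
                raise ValueError("weights must align with points")

    def __len__(self) -> int:
        return len(self.points)


def _sample_angles(spec: EllipsoidSpec) -> tuple[np.ndarray, np.ndarray]:
    # interval midpoints: theta in (0, pi), phi in (0, 2 pi); no duplicated poles
    theta = (np.arange(spec.n_theta) + 0.5) * np.pi / spec.n_theta
    phi = (np.arange(spec.n_phi) + 0.5) * 2.0 * np.pi / spec.n_phi
    return theta, phi


def ellipsoid_points(spec: EllipsoidSpec) -> PointCloud:
    """Sample the ellipsoid surface on a theta x phi grid of interval midpoints.

    Point (i, j) lies at spherical angles (theta_i, phi_j); row-major (i, j)
    ordering is deterministic, giving a stable index correspondence across
    ellipsoids sampled on the same grid.
    """
    theta, phi = _sample_angles(spec)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    st = np.sin(tt.ravel())
    pts = np.column_stack([
        spec.a * st * np.cos(pp.ravel()),
        spec.b * st * np.sin(pp.ravel()),
        spec.c * np.cos(tt.ravel()),
    ])
    key = f"ellipsoid:{spec.n_theta}x{spec.n_phi}"
    return PointCloud(points=pts, correspondence_key=key)


def ellipsoid_mesh(spec: EllipsoidSpec) -> trimesh.Trimesh:
    """Closed triangulation of the sampling grid, with two pole vertices.

    Grid quads are split into triangles; polar gaps left by midpoint sampling
    are closed with triangle fans to the poles, so the mesh is watertight.
    """
    cloud = ellipsoid_points(spec)
    nt, np_ = spec.n_theta, spec.n_phi
    verts = np.vstack([cloud.points, [0.0, 0.0, spec.c], [0.0, 0.0, -spec.c]])
    top, bottom = nt * np_, nt * np_ + 1
    faces = []
    for i in range(nt - 1):
        for j in range(np_):
            j2 = (j + 1) % np_
            v00, v01 = i * np_ + j, i * np_ + j2
            v10, v11 = (i + 1) * np_ + j, (i + 1) * np_ + j2
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    for j in range(np_):  # pole fans (theta_0 ring -> +c pole, last ring -> -c)
        j2 = (j + 1) % np_
        faces.append([top, j, j2])
        faces.append([bottom, (nt - 1) * np_ + j2, (nt - 1) * np_ + j])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    return mesh


def ellipsoid_series(count: int = 20, ecc_max: float = 0.92,
                     n_theta: int = 50, n_phi: int = 50) -> list[EllipsoidSpec]:
    """Prolate spheroids (b = c = 1) with eccentricities evenly spaced 0..ecc_max.

    With b = c the eccentricity formula reduces to the classical
    sqrt(1 - c^2/a^2), so a = 1/sqrt(1 - e^2).  The first element is a sphere.
    """
    if count < 2:
        raise ValueError("count must be at least 2")
    if not (0.0 <= ecc_max < 1.0):
        raise ValueError("ecc_max must lie in [0, 1)")
    eccs = np.linspace(0.0, ecc_max, count)
    return [
        EllipsoidSpec(a=1.0 / np.sqrt(1.0 - e**2), b=1.0, c=1.0,
                      n_theta=n_theta, n_phi=n_phi)
        for e in eccs
    ]


def torus_mesh(R: float, r: float, segments: int = 64) -> trimesh.Trimesh:
    """Watertight genus-1 torus with major radius R and minor radius r."""
    if segments < 3:
        raise ValueError("segments must be at least 3")
    if not (R > r > 0):
        raise ValueError(f"need R > r > 0 for a non-self-intersecting torus, "
                         f"got R={R}, r={r}")
    mesh = trimesh.creation.torus(
        major_radius=R, minor_radius=r,
        major_sections=segments, minor_sections=max(segments // 2, 3),
    )
    mesh.fix_normals()
    return mesh


def sphere_mesh(radius: float = 1.0, subdivisions: int = 3) -> trimesh.Trimesh:
    """Watertight icosphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)


def cube_mesh(edge: float = 1.0) -> trimesh.Trimesh:
    """Watertight axis-aligned cube centered at the origin."""
    if edge <= 0:
        raise ValueError("edge must be positive")
    return trimesh.creation.box(extents=(edge, edge, edge))


def blob_atoms(n_lobes: int = 2, atoms_per_lobe: int = 50, seed: int = 0,
               lobe_sigma: float = 3.0, lobe_separation: float = 12.0):
    """Multi-lobe Gaussian pseudo-atom cloud mimicking multi-domain shapes.

    Lobe centers are spread on a circle of radius ``lobe_separation/2`` so
    lobes stay separated; atoms are drawn i.i.d. normal around each center
    with spread ``lobe_sigma`` (Angstrom).  Deterministic for a given seed.
    Returns an AtomSet with a fixed 1.7 A van der Waals radius per atom.
    """
    from .structure_io import AtomSet

    if n_lobes < 1 or atoms_per_lobe < 1:
        raise ValueError("n_lobes and atoms_per_lobe must be positive")
    rng = np.random.default_rng(seed)
    ang = 2.0 * np.pi * np.arange(n_lobes) / max(n_lobes, 2)
    centers = 0.5 * lobe_separation * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(n_lobes)])
    coords = np.vstack([
        c + lobe_sigma * rng.standard_normal((atoms_per_lobe, 3)) for c in centers
    ])
    n = len(coords)
    return AtomSet(
        coordinates=coords,
        elements=np.array(["C"] * n),
        radii=np.full(n, PSEUDO_ATOM_RADIUS),
        chain_ids=np.array(["A"] * n),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.array(["BLB"] * n),
    )
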