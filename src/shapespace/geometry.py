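"""Geometric shape statistics: MVEE eccentricity, volumes, genus, donut screen.

The eccentricity of a shape is derived from its minimum-volume enclosing
ellipsoid (MVEE) with semi-axes a >= b >= c:

    eccentricity = sqrt((2 - b^2/a^2 - c^2/a^2) / 2)

(0 for a sphere, approaching 1 for elongated shapes).  Surface topology uses
the Euler--Poincare relation V + F - E - (L - F) = 2 (S - g), with L = F for
triangle meshes; S counts face-connected shells.  Ring (donut) shapes are
flagged by genus > 0 together with a near-circular, flattened MVEE cross
section.  Vp/Vc compares the enclosed surface volume with the convex hull
volume; values well below 1 indicate protrusions, hollows or holes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.spatial
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .surface_voxel import DegenerateInputError

__all__ = [
    "MVEEResult",
    "GeometryReport",
    "mvee",
    "eccentricity",
    "mesh_volume",
    "convex_hull_volume",
    "genus",
    "donut_screen",
    "procrustes_distance",
    "geometry_report",
]


@dataclass
class MVEEResult:
    """Minimum-volume enclosing ellipsoid: center, semi-axes a>=b>=c, rotation.

    ``rotation`` columns are the principal directions matching the sorted
    semi-axes; a point p is inside iff |R^T (p - center) / axes| <= 1.
    """

    center: np.ndarray
    semi_axes: np.ndarray  # descending (a, b, c)
    rotation: np.ndarray

    @property
    def a(self) -> float:
        return float(self.semi_axes[0])

    @property
    def b(self) -> float:
        return float(self.semi_axes[1])

    @property
    def c(self) -> float:
        return float(self.semi_axes[2])


@dataclass
class GeometryReport:
    """Per-shape geometric summary used for the shape-space analyses."""

    eccentricity: float
    vp: float
    vc: float
    ratio: float
    genus: int
    shells: int
    donut: bool
    mvee_axes: tuple[float, float, float]

    def to_dict(self) -> dict:
        return asdict(self)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(getattr(points, "points", points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) point array")
    return pts


def mvee(points, tolerance: float = 1e-4, max_iter: int = 10000) -> MVEEResult:
    """Minimum-volume enclosing ellipsoid by Khachiyan's barycentric ascent.

    Iterates weights u over the points until the most-violating point's
    Mahalanobis score exceeds the dimension bound by less than ``tolerance``;
    every input point is inside the returned ellipsoid within (1 + tolerance).
    """
    pts = _as_points(points)
    n, d = pts.shape
    if n < 4:
        raise DegenerateInputError("MVEE needs at least 4 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 3:
        raise DegenerateInputError(
            "points are degenerate (collinear or coplanar); MVEE is undefined")

    q = np.column_stack([pts, np.ones(n)])          # lifted points, (n, 4)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x = q.T @ (q * u[:, None])                   # (4, 4)
        m = np.einsum("ij,ji->i", q, np.linalg.solve(x, q.T))
        j = int(np.argmax(m))
        max_m = m[j]
        if max_m <= (d + 1) * (1.0 + tolerance):
            break
        step = (max_m - d - 1.0) / ((d + 1.0) * (max_m - 1.0))
        u *= 1.0 - step
        u[j] += step

    center = u @ pts
    cov = pts.T @ (pts * u[:, None]) - np.outer(center, center)
    shape_matrix = np.linalg.inv(cov) / d            # (x-c)^T A (x-c) <= 1
    eigval, eigvec = np.linalg.eigh(shape_matrix)
    axes = 1.0 / np.sqrt(np.maximum(eigval, 1e-300))
    order = np.argsort(axes)[::-1]
    axes, eigvec = axes[order], eigvec[:, order]
    if np.linalg.det(eigvec) < 0:
        eigvec[:, -1] *= -1.0
    return MVEEResult(center=center, semi_axes=axes, rotation=eigvec)


def eccentricity(result: MVEEResult) -> float:
    """sqrt((2 - b^2/a^2 - c^2/a^2)/2) from sorted MVEE semi-axes, in [0, 1]."""
    a, b, c = result.a, result.b, result.c
    val = (2.0 - b**2 / a**2 - c**2 / a**2) / 2.0
    return float(np.sqrt(np.clip(val, 0.0, 1.0)))


def _edge_census(faces: np.ndarray):
    """Unique undirected edges, their face incidence counts, and edge ids per face."""
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
        axis=1)
    uniq, inverse, counts = np.unique(edges, axis=0, return_inverse=True,
                                      return_counts=True)
    return uniq, inverse, counts


def mesh_volume(mesh) -> float:
    """Enclosed volume of a watertight triangle mesh (divergence theorem).

    Inward-oriented meshes yield the same (positive) value; non-watertight
    meshes are rejected with the number of open edges.
    """
    faces = np.asarray(mesh.faces)
    _, _, counts = _edge_census(faces)
    open_edges = int((counts != 2).sum())
    if open_edges:
        raise ValueError(f"mesh is not watertight: {open_edges} open edges")
    v = np.asarray(mesh.vertices, dtype=float)
    t = v[faces]
    signed = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    return abs(float(signed))


def convex_hull_volume(points) -> float:
    """Volume of the convex hull of a point set (scipy ConvexHull)."""
    pts = _as_points(points)
    try:
        return float(scipy.spatial.ConvexHull(pts).volume)
    except scipy.spatial.QhullError as exc:
        raise DegenerateInputError(f"degenerate input for convex hull: {exc}")


def genus(mesh) -> tuple[int, int]:
    """(genus g, shell count S) of a closed triangle mesh via Euler--Poincare.

    With V vertices, E unique edges, F faces and L = F loops,
    V + F - E - (L - F) = 2 (S - g); S is the number of face-connected
    components (faces linked through shared edges).
    """
    faces = np.asarray(mesh.faces)
    if len(faces) == 0:
        raise ValueError("mesh has no faces")
    uniq_edges, inverse, counts = _edge_census(faces)
    open_edges = int((counts != 2).sum())
    if open_edges:
        raise ValueError(f"mesh is not closed: {open_edges} open edges")

    n_faces = len(faces)
    edge_of_face = inverse.reshape(3, n_faces).T  # edge ids per face
    # connect faces sharing an edge: each edge has exactly 2 incident faces,
    # so stable-sorting flat (edge id -> face id) pairs groups them in twos
    order = np.argsort(edge_of_face.ravel(), kind="stable")
    face_ids = np.repeat(np.arange(n_faces), 3).ravel()[order].reshape(-1, 2)
    adj = coo_matrix(
        (np.ones(len(face_ids)), (face_ids[:, 0], face_ids[:, 1])),
        shape=(n_faces, n_faces))
    shells, _ = connected_components(adj, directed=False)

    n_vertices = len(np.unique(faces))
    n_edges = len(uniq_edges)
    euler = n_vertices + n_faces - n_edges        # L = F cancels the loop term
    g = shells - euler // 2
    if euler % 2 != 0 or g < 0:
        raise ValueError("inconsistent mesh topology")
    return int(g), int(shells)


def donut_screen(g: int, result: MVEEResult) -> bool:
    """Ring-shape screen: genus > 0, near-circular cross section, flattened.

    Requires 0.9 <= b/a <= 1.0 and (c^2/a^2 + c^2/b^2)/2 <= 0.6.
    """
    a, b, c = result.a, result.b, result.c
    flat = (c**2 / a**2 + c**2 / b**2) / 2.0
    return bool(g > 0 and 0.9 <= b / a <= 1.0 and 0.0 <= flat <= 0.6)


def procrustes_distance(p, q) -> float:
    """RMSD between index-corresponding point sets after optimal similarity
    alignment (translation, rotation, scaling).

    Both clouds are standardized (centered, unit Frobenius norm) before the
    optimal rotation, making the distance symmetric in its arguments.
    """
    pa, qa = _as_points(p), _as_points(q)
    if pa.shape != qa.shape:
        raise ValueError(f"point count mismatch: {pa.shape[0]} vs {qa.shape[0]}")
    _, _, disparity = scipy.spatial.procrustes(pa, qa)
    return float(np.sqrt(disparity / len(pa)))


def geometry_report(mesh, points=None, mvee_tolerance: float = 1e-4) -> GeometryReport:
    """Full geometric summary of a shape.

    MVEE/eccentricity uses ``points`` when given (e.g. all atoms of a
    structure), else the mesh vertices.  Vp is the mesh-enclosed volume and
    Vc the convex hull volume of the mesh vertices — the hull of the same
    body whose volume is measured, so Vp <= Vc holds structurally.
    """
    pts = _as_points(points) if points is not None else np.asarray(mesh.vertices)
    ell = mvee(pts, tolerance=mvee_tolerance)
    ecc = eccentricity(ell)
    vp = mesh_volume(mesh)
    vc = convex_hull_volume(np.asarray(mesh.vertices))
    g, shells = genus(mesh)
    return GeometryReport(
        eccentricity=ecc, vp=vp, vc=vc, ratio=vp / vc, genus=g, shells=shells,
        donut=donut_screen(g, ell),
        mvee_axes=(ell.a, ell.b, ell.c),
    )
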