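"""3D Zernike moments and rotation-invariant shape descriptors.

A binary voxel shell is treated as a function ``f(x)`` supported on the unit
ball and expanded in the Zernike--Canterakis basis

    Z_nlm(r, theta, phi) = R_nl(r) * Y_lm(theta, phi),

with 0 <= l <= n, (n - l) even and -l <= m <= l.  ``Y_lm`` are orthonormal
complex spherical harmonics and ``R_nl`` are the Canterakis radial
polynomials, here normalized so that the ``Z_nlm`` are orthonormal on the
unit ball, i.e. the integral of ``Z_nlm * conj(Z_n'l'm')`` over ``|x| <= 1``
equals ``delta_nn' delta_ll' delta_mm'``.

Moments are computed as

    Omega_nlm = 3/(4 pi) * sum_i w_i * conj(Z_nlm(x_i))

over occupied voxel centers ``x_i`` mapped into the unit ball with uniform
weights ``w_i = 1/n_occupied``.  Rotation-invariant descriptors are the
per-(n, l) Euclidean norms over m:

    F_nl = sqrt( sum_m |Omega_nlm|^2 ).

At order 20 this yields a vector of 121 invariants.  Shapes are compared by
the plain Euclidean distance between descriptor vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_jacobi

from .surface_voxel import VoxelGrid, grid_to_unit_ball

__all__ = [
    "ZernikeMoments",
    "ZernikeDescriptor",
    "radial_poly",
    "invariant_count",
    "nl_index_map",
    "compute_moments",
    "moments_from_points",
    "invariants",
    "descriptor_distance",
    "DEFAULT_ORDER",
]

DEFAULT_ORDER = 20
_NORM = 3.0 / (4.0 * np.pi)


def _check_nl(n: int, l: int) -> None:
    if n < 0 or l < 0 or l > n:
        raise ValueError(f"invalid Zernike index (n={n}, l={l}): need 0 <= l <= n")
    if (n - l) % 2 != 0:
        raise ValueError(f"invalid Zernike index (n={n}, l={l}): (n - l) must be even")


def radial_poly(n: int, l: int, r):
    """Canterakis radial polynomial R_nl evaluated at radii ``r`` in [0, 1].

    Expressed through Jacobi polynomials,
    ``R_nl(r) = sqrt(2n+3) * r^l * P_k^(0, l+1/2)(2 r^2 - 1)`` with
    ``k = (n-l)/2``; the prefactor makes the family orthonormal with respect
    to ``r^2 dr`` on [0, 1], and ``R_nl(1) = sqrt(2n+3) > 0`` fixes the sign.
    """
    _check_nl(n, l)
    r = np.asarray(r, dtype=float)
    k = (n - l) // 2
    return np.sqrt(2 * n + 3) * r**l * eval_jacobi(k, 0.0, l + 0.5, 2.0 * r**2 - 1.0)


def invariant_count(n_max: int) -> int:
    """Number of (n, l) invariant pairs up to order ``n_max`` (121 at order 20)."""
    if n_max < 0:
        raise ValueError("order must be nonnegative")
    return len(nl_index_map(n_max))


def nl_index_map(n_max: int) -> list[tuple[int, int]]:
    """Lexicographic (n asc, l asc) ordering of valid (n, l) pairs."""
    if n_max < 0:
        raise ValueError("order must be nonnegative")
    return [(n, l) for n in range(n_max + 1) for l in range(n % 2, n + 1, 2)]


@dataclass
class ZernikeMoments:
    """Complex moments Omega_nlm keyed by (n, l), each an array over m=-l..l."""

    n_max: int
    omega: dict[tuple[int, int], np.ndarray]

    def get(self, n: int, l: int, m: int) -> complex:
        _check_nl(n, l)
        if abs(m) > l:
            raise ValueError(f"|m| must not exceed l (m={m}, l={l})")
        return complex(self.omega[(n, l)][m + l])


@dataclass
class ZernikeDescriptor:
    """Rotation-invariant descriptor: F_nl values in lexicographic (n, l) order."""

    n_max: int
    values: np.ndarray
    index_map: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.index_map:
            self.index_map = nl_index_map(self.n_max)
        if self.values.shape != (len(self.index_map),):
            raise ValueError(
                f"descriptor length {self.values.size} does not match "
                f"invariant_count({self.n_max}) = {len(self.index_map)}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("descriptor values must be finite and nonnegative")

    def __len__(self) -> int:
        return self.values.size


def _spherical_harmonics_conj(n_max: int, cos_theta: np.ndarray,
                              phi: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """conj(Y_lm) for all 0 <= m <= l <= n_max via the normalized associated
    Legendre recurrence (Condon--Shortley phase, orthonormal on the sphere)."""
    x = cos_theta
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, 1.0))  # sin(theta)
    # fully normalized P_lm including the 1/sqrt(4 pi) harmonic prefactor
    p: dict[tuple[int, int], np.ndarray] = {}
    p[(0, 0)] = np.full_like(x, 0.5 / np.sqrt(np.pi))
    for m in range(1, n_max + 1):
        # diagonal term: P_mm = -sqrt((2m+1)/(2m)) * sin(theta) * P_(m-1)(m-1)
        p[(m, m)] = -np.sqrt((2 * m + 1.0) / (2.0 * m)) * s * p[(m - 1, m - 1)]
    for m in range(n_max):
        p[(m + 1, m)] = np.sqrt(2 * m + 3.0) * x * p[(m, m)]
    for m in range(n_max + 1):
        for l in range(m + 2, n_max + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            p[(l, m)] = a * (x * p[(l - 1, m)] - b * p[(l - 2, m)])
    # e^{-i m phi} built multiplicatively
    out: dict[tuple[int, int], np.ndarray] = {}
    e_neg = np.exp(-1j * phi)
    em = np.ones_like(e_neg)
    for m in range(n_max + 1):
        if m > 0:
            em = em * e_neg
        for l in range(m, n_max + 1):
            out[(l, m)] = p[(l, m)] * em
    return out


_CHUNK = 120_000  # points per accumulation chunk (bounds peak memory)


def moments_from_points(
    points: np.ndarray, weights: np.ndarray, n_max: int = DEFAULT_ORDER
) -> ZernikeMoments:
    """Moments of a weighted point mass distribution inside the unit ball.

    Negative-m moments are filled from the conjugate symmetry
    ``Omega_nl,-m = (-1)^m conj(Omega_nlm)`` that holds for real densities.
    Points are processed in fixed-size chunks so memory stays bounded for
    large voxel shells.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] == 0:
        raise ValueError("points must be a nonempty (n, 3) array")
    r_all = np.linalg.norm(points, axis=1)
    if np.any(r_all > 1.0 + 1e-9):
        raise ValueError("all points must lie inside the unit ball")

    omega: dict[tuple[int, int], np.ndarray] = {
        (n, l): np.zeros(2 * l + 1, dtype=complex)
        for l in range(n_max + 1) for n in range(l, n_max + 1, 2)
    }
    for start in range(0, len(points), _CHUNK):
        sl = slice(start, start + _CHUNK)
        pts, w, r = points[sl], weights[sl], r_all[sl]
        # direction cosines; the origin gets an arbitrary (irrelevant) direction
        safe_r = np.where(r > 0, r, 1.0)
        cos_theta = np.clip(pts[:, 2] / safe_r, -1.0, 1.0)
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        y_conj = _spherical_harmonics_conj(n_max, cos_theta, phi)
        for l in range(n_max + 1):
            ns = list(range(l, n_max + 1, 2))
            # weighted radial stack shared across m: (num_n, chunk)
            radial = np.vstack([radial_poly(n, l, r) * w for n in ns])
            for m in range(l + 1):
                vals = _NORM * (radial @ y_conj[(l, m)])
                for n, val in zip(ns, vals):
                    omega[(n, l)][m + l] += val
            for m in range(l + 1):
                del y_conj[(l, m)]
    for (n, l), row in omega.items():
        for m in range(1, l + 1):
            row[l - m] = (-1) ** m * np.conj(row[m + l])
    return ZernikeMoments(n_max=n_max, omega=omega)


def compute_moments(
    grid: VoxelGrid, n_max: int = DEFAULT_ORDER, fill_fraction: float = 0.7,
    reference_radius: float | None = None,
) -> ZernikeMoments:
    """Zernike moments of a voxel grid's occupied cells, unit-ball mapped.

    ``reference_radius`` is forwarded to the unit-ball mapping to compute a
    cohort of grids at one common scale instead of per-shape scaling.
    """
    cloud = grid_to_unit_ball(grid, fill_fraction=fill_fraction,
                              reference_radius=reference_radius)
    return moments_from_points(cloud.points, cloud.weights, n_max=n_max)


def invariants(moments: ZernikeMoments) -> ZernikeDescriptor:
    """Collapse moments to rotation invariants F_nl = ||Omega_nl||_2 over m."""
    idx = nl_index_map(moments.n_max)
    values = np.array(
        [np.sqrt(np.sum(np.abs(moments.omega[(n, l)]) ** 2)) for n, l in idx]
    )
    return ZernikeDescriptor(n_max=moments.n_max, values=values, index_map=idx)


def descriptor_distance(x: ZernikeDescriptor, y: ZernikeDescriptor) -> float:
    """Euclidean distance d_E between two descriptors of equal order."""
    if x.n_max != y.n_max:
        raise ValueError(f"descriptor order mismatch: {x.n_max} != {y.n_max}")
    return float(np.linalg.norm(x.values - y.values))
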