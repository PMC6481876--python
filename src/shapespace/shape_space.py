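"""Shape-space mapping: PCA of descriptor vectors and map-level statistics.

Descriptor vectors (121 invariants at order 20) are centered and projected
onto the top three principal components of their covariance matrix; in the
resulting 3D map, proximity encodes surface-shape similarity.  Trends along
a principal axis are summarized with a sliding cylinder (default radius 2.0,
height 0.5, stepped at 0.5 axis units): at each bin center, a property is
averaged over shapes inside the cylinder.  Two cohorts mapped into a common
space are compared by segmenting the space into unit cubes and counting
cubes occupied by either or both cohorts; class enrichments are assessed
with a Pearson chi-square test on 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2_contingency, pearsonr
from sklearn.decomposition import PCA

from .zernike import ZernikeDescriptor

__all__ = [
    "ShapeSpaceMap",
    "AxisProfile",
    "RegressionResult",
    "fit_map",
    "scree",
    "axis_profile",
    "axis_regression",
    "cube_occupancy",
    "enrichment_test",
    "CYLINDER_RADIUS",
    "CYLINDER_HEIGHT",
    "PROFILE_STEP",
]

CYLINDER_RADIUS = 2.0
CYLINDER_HEIGHT = 0.5
PROFILE_STEP = 0.5
_N_COMPONENTS = 3


@dataclass
class ShapeSpaceMap:
    """3D PCA embedding of a descriptor cohort."""

    ids: list[str]
    coordinates: np.ndarray          # (n, 3), PC units
    eigenvalues: np.ndarray          # descending, padded to descriptor length
    loadings: np.ndarray             # (3, n_features)
    explained_fraction: np.ndarray   # per retained component
    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_shapes(self) -> int:
        return len(self.ids)

    def project(self, descriptors: Sequence[ZernikeDescriptor]) -> np.ndarray:
        """Project additional descriptors into this fitted space."""
        x = np.vstack([d.values for d in descriptors])
        return (x - self.mean) @ self.loadings.T


@dataclass
class AxisProfile:
    """Sliding-cylinder aggregate of a per-shape property along one PC axis."""

    axis: int
    bin_centers: np.ndarray
    aggregate: np.ndarray      # NaN where the bin is empty
    counts: np.ndarray
    shape_values: np.ndarray   # per-shape property values (for per-shape r)
    shape_coords: np.ndarray   # per-shape coordinate on the profiled axis


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r: float           # Pearson r between bin centers and bin aggregates
    r_per_shape: float  # Pearson r between per-shape coordinates and values


def fit_map(descriptors: Sequence[ZernikeDescriptor],
            ids: Sequence[str] | None = None) -> ShapeSpaceMap:
    """PCA of centered descriptor vectors, keeping the top 3 components.

    Sign convention: each component is flipped, if needed, so its
    largest-magnitude loading is positive; refitting the same cohort yields
    bit-identical coordinates.
    """
    if len(descriptors) < 4:
        raise ValueError("need at least 4 descriptors to fit a map")
    orders = {d.n_max for d in descriptors}
    if len(orders) != 1:
        raise ValueError(f"descriptors have mixed orders: {sorted(orders)}")
    x = np.vstack([d.values for d in descriptors])
    n, p = x.shape
    pca = PCA(n_components=min(n, p), svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero-variance cohorts are legal
        scores = pca.fit_transform(x)

    eigenvalues = np.zeros(p)
    eigenvalues[: len(pca.explained_variance_)] = pca.explained_variance_
    loadings = pca.components_[:_N_COMPONENTS].copy()
    coords = scores[:, :_N_COMPONENTS].copy()
    if loadings.shape[0] < _N_COMPONENTS:  # degenerate cohorts (rank < 3)
        pad = _N_COMPONENTS - loadings.shape[0]
        loadings = np.vstack([loadings, np.zeros((pad, p))])
        coords = np.hstack([coords, np.zeros((n, pad))])
    for k in range(_N_COMPONENTS):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            coords[:, k] *= -1.0
    total = eigenvalues.sum()
    explained = eigenvalues[:_N_COMPONENTS] / total if total > 0 else np.zeros(3)
    if ids is None:
        ids = [f"shape_{i}" for i in range(n)]
    return ShapeSpaceMap(
        ids=list(ids), coordinates=coords, eigenvalues=eigenvalues,
        loadings=loadings, explained_fraction=explained, mean=pca.mean_,
    )


def scree(space_map: ShapeSpaceMap, k: int = 10) -> np.ndarray:
    """First ``k`` covariance eigenvalues, descending."""
    if k < 1 or k > len(space_map.eigenvalues):
        raise ValueError(
            f"k must lie in [1, {len(space_map.eigenvalues)}], got {k}")
    return space_map.eigenvalues[:k].copy()


def axis_profile(space_map: ShapeSpaceMap, axis: int, values: Sequence[float],
                 radius: float = CYLINDER_RADIUS, height: float = CYLINDER_HEIGHT,
                 step: float = PROFILE_STEP) -> AxisProfile:
    """Sliding-cylinder mean of ``values`` along a principal axis.

    A shape contributes to the bin at center t iff its coordinate on
    ``axis`` lies within height/2 of t and its distance in the two
    orthogonal PC dimensions is at most ``radius``.  Empty bins carry NaN.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis!r}")
    values = np.asarray(values, dtype=float)
    if values.shape != (space_map.n_shapes,):
        raise ValueError("values must align with the map's shapes")
    coords = space_map.coordinates
    axis_coord = coords[:, axis]
    ortho = coords[:, [k for k in range(3) if k != axis]]
    ortho_dist = np.linalg.norm(ortho, axis=1)

    t0 = np.floor(axis_coord.min() / step) * step
    t1 = np.ceil(axis_coord.max() / step) * step
    centers = np.arange(t0, t1 + step / 2, step)
    aggregate = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for i, t in enumerate(centers):
        member = (np.abs(axis_coord - t) <= height / 2) & (ortho_dist <= radius)
        counts[i] = member.sum()
        if counts[i]:
            aggregate[i] = values[member].mean()
    return AxisProfile(axis=axis, bin_centers=centers, aggregate=aggregate,
                       counts=counts, shape_values=values,
                       shape_coords=axis_coord)


def axis_regression(profile: AxisProfile) -> RegressionResult:
    """OLS of bin aggregates on bin centers, plus Pearson correlations.

    ``r`` is the correlation over nonempty bins (matching trend-figure
    captions); ``r_per_shape`` is over the underlying per-shape pairs.
    """
    ok = ~np.isnan(profile.aggregate)
    if ok.sum() < 3:
        raise ValueError("need at least 3 nonempty bins for a regression")
    x, y = profile.bin_centers[ok], profile.aggregate[ok]
    slope, intercept = np.polyfit(x, y, 1)
    r = float(pearsonr(x, y).statistic) if np.ptp(y) > 0 else 0.0
    if np.ptp(profile.shape_values) > 0 and np.ptp(profile.shape_coords) > 0:
        r_shape = float(pearsonr(profile.shape_coords,
                                 profile.shape_values).statistic)
    else:
        r_shape = 0.0
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r=r, r_per_shape=r_shape)


def cube_occupancy(coords_a: np.ndarray, coords_b: np.ndarray,
                   edge: float = 1.0) -> tuple[float, float, float]:
    """Fractions of occupied unit-lattice cubes shared / A-only / B-only.

    The space is segmented into cubes of ``edge`` axis units anchored at the
    origin; a cube is occupied by a cohort if it contains at least one of
    its points.  Fractions are over the union of occupied cubes and sum to 1.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both coordinate sets must be nonempty")
    if edge <= 0:
        raise ValueError("cube edge must be positive")
    cubes_a = {tuple(c) for c in np.floor(a / edge).astype(int)}
    cubes_b = {tuple(c) for c in np.floor(b / edge).astype(int)}
    union = len(cubes_a | cubes_b)
    shared = len(cubes_a & cubes_b)
    return (shared / union,
            len(cubes_a - cubes_b) / union,
            len(cubes_b - cubes_a) / union)


def enrichment_test(counts) -> tuple[float, float]:
    """Pearson chi-square test (1 df, no continuity correction) on a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or not np.all(
            table == np.round(table)):
        raise ValueError("counts must be a 2x2 table of nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero marginal; test undefined")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
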