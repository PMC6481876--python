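# Methods

`shapespace` maps the global surface shape of protein structures (single
chains or biological assemblies) and synthetic geometric bodies into a
common descriptor space, and summarizes each shape with a small set of
geometric statistics. This note records the models, the conventions chosen
where the literature leaves them open, and the known limitations.

## Surface shell representation

A shape enters the pipeline either as a triangle mesh or as an atom set.
For atoms, a molecular surface is built as a Gaussian-density isosurface:
each atom contributes `exp(-beta * ((|x - x_i| / (r_i + p))^2 - 1))` with
`beta = 2.3`, van der Waals radius `r_i` and probe radius `p` (default 0,
giving a van-der-Waals-like envelope; `p = 1.4` approximates a
solvent-inflated one). The level-1 isosurface of the summed density is
extracted by marching cubes on a grid of ~0.5 Å spacing. This is a
*surface substitute*: it produces a closed, watertight envelope with the
same qualitative features as solvent-excluded surfaces from rolling-probe
programs, but is not identical to them; volume ratios computed from it
carry a small systematic offset (the rolling-probe programs themselves
disagree with each other by about 1% on average). Surface components that
lie entirely inside another component — the walls of buried cavities — are
discarded, so only solvent-reachable surface is described.

The mesh is then voxelized into a binary shell: the mesh bounding box is
centered in an `N^3` grid (default `N = 200`) and uniformly scaled so its
largest extent spans `N - 4` voxels; a voxel is set to 1 iff its center
lies closer than 1.7 grid intervals to any surface triangle (exact
point-to-triangle distances). The shell is hollow — no interior fill — so
the descriptor characterizes the surface, not the solid.

## 3D Zernike descriptors

The occupied voxel centers, translated to their centroid and scaled so the
farthest sits at radius 0.7 of the unit ball (`fill_fraction`, configurable;
0.7 suppresses boundary artifacts of the radial basis), define a weighted
point distribution with uniform weights `1/n_occupied`. Its moments in the
Zernike–Canterakis basis are

    Omega_nlm = 3/(4 pi) * sum_i w_i * conj(Z_nlm(x_i)),
    Z_nlm = R_nl(r) Y_lm(theta, phi),

with `0 <= l <= n`, `n - l` even. The basis here is orthonormal on the unit
ball: `Y_lm` are orthonormal spherical harmonics (Condon–Shortley phase)
and `R_nl(r) = sqrt(2n+3) r^l P_k^(0, l+1/2)(2r^2 - 1)`, `k = (n-l)/2`,
expressed through Jacobi polynomials. Rotation-invariant descriptors are
the norms `F_nl = ||Omega_nl.||_2` over `m`; at order 20 this gives 121
invariants, compared between shapes by plain Euclidean distance `d_E`.
Uniform voxel weights make `F_00` a constant, so descriptors are
size-comparable across shapes and the distance reflects shape, not volume.

Implementation: harmonics are evaluated by the normalized associated
Legendre recurrence and radial polynomials via `scipy` Jacobi evaluation,
vectorized over voxels in fixed-size chunks (bounded memory; ~10 s for a
`N = 200` shell at order 20 on one core). The test suite cross-checks this
engine against a fully independent construction (Gram–Schmidt
orthogonalization of monomials plus `scipy` harmonics, direct quadrature)
to 1e-6 relative, and verifies exact invariance under the 24 cubic
rotations (observed discrepancy ~1e-15 relative).

Because moments are quadrature sums over a binary lattice, descriptors of a
perfectly spherical shell are not exactly zero for `l > 0`: the lattice
noise floor is `max F_nl / F_00 ≈ 1.5 / sqrt(n_occupied)` (about 3e-3 for a
`N = 200`, thickness-1.7 shell). This floor is far below the anisotropy
signal of any structured shape, but it bounds how clean a "spherical null"
can be at practical grid sizes.

## Geometric shape statistics

- **Eccentricity.** The minimum-volume enclosing ellipsoid (MVEE) of all
  atoms (or mesh vertices) is found by Khachiyan's barycentric ascent
  (tolerance 1e-4, at most 10,000 iterations); with sorted semi-axes
  `a >= b >= c`, eccentricity is `sqrt((2 - b^2/a^2 - c^2/a^2)/2)` — 0 for
  a sphere, approaching 1 for elongated shapes.
- **Volume ratio.** `Vp` is the enclosed volume of the watertight surface
  mesh (signed tetrahedra; orientation-insensitive), `Vc` the convex hull
  volume of the same points (Qhull). `Vp/Vc <= 1`, with low values
  indicating protrusions, hollows or holes.
- **Genus.** For a closed triangle mesh, `V + F - E - (L - F) = 2 (S - g)`
  with `L = F`; `S` counts face-connected shells. Open meshes are rejected
  with their open-edge count rather than silently patched.
- **Donut screen.** A shape is flagged ring-like iff `g > 0`,
  `0.9 <= b/a <= 1.0` and `(c^2/a^2 + c^2/b^2)/2 <= 0.6` on its MVEE.
- **Procrustes distance.** For point sets with index correspondence, both
  clouds are standardized (centered, unit Frobenius norm), the optimal
  rotation applied, and the RMSD of corresponding points reported. Scaling
  both clouds (rather than one onto the other) makes the distance symmetric.

## Shape-space mapping

Descriptor vectors are centered and projected onto the top three principal
components of their covariance; eigenvalues are reported for all 121
dimensions (zero-padded when the cohort is smaller). Component signs are
fixed by making each component's largest-magnitude loading positive, so
repeated fits are bit-identical. Axis trends use a sliding cylinder
(radius 2.0, height 0.5, stepped at 0.5 PC units): a property is averaged
over shapes inside the cylinder at each bin center; empty bins are NaN, not
zero. Trend regressions are ordinary least squares of bin aggregate on bin
center, reporting both the bin-level Pearson r (what trend-figure captions
quote) and the per-shape r. Cohort overlap segments the 3D map into cubes
(edge 1.0, lattice anchored at the origin) and reports shared / A-only /
B-only fractions of occupied cubes. Class enrichment uses the Pearson
chi-square test on 2×2 tables, 1 df, no continuity correction, and no
multiple-testing adjustment.

## The ellipsoid benchmark

`ellipsoid_benchmark` builds 20 prolate spheroids (`b = c = 1`,
`a = 1/sqrt(1 - e^2)`) with eccentricities evenly spaced from 0.0 to 0.92,
samples 2,500 surface points per shape at the midpoints of a 50×50
(theta, phi) grid (midpoint sampling avoids duplicated pole points; the
stable (i, j) ordering provides exact point correspondence), triangulates
the grid with two pole fans into a watertight mesh, and runs the full
descriptor pipeline at grid 128, order 20. It then correlates the 190
pairwise descriptor distances against the 190 pairwise Procrustes
distances.

Two conventions here were genuinely open and are worth stating:

- *Prolate family.* Only the eccentricity endpoints are fixed by the
  design; prolate spheroids are the simplest family for which the
  eccentricity formula reduces to the classical `sqrt(1 - c^2/a^2)`.
- *Cohort-common frame.* The series is voxelized at a single scale (that
  of the largest ellipsoid) and mapped into the unit ball with a single
  reference radius, so the size growth along the series is part of the
  descriptor signal. With per-shape scaling the descriptor distance becomes
  scale-free while the Procrustes distance remains convex in eccentricity,
  and the correlation saturates near 0.89 regardless of grid size; the
  common frame restores the size component and yields r ≈ 0.96 at grid
  128 (rank correlation 0.997). The production pipeline for heterogeneous
  cohorts keeps per-shape scaling.

## Synthetic data

The generators produce everything the test-bed needs without downloads:
the ellipsoid series above; watertight icospheres, boxes and tori (genus-1
fixtures); and multi-lobe pseudo-protein atom clouds (Gaussian clusters of
1.7 Å pseudo-atoms around separated lobe centers, deterministic per seed).
These emulate the *global* geometry of proteins — size, lobedness,
elongation, handles — but none of the local texture of real molecular
surfaces (side-chain corrugation, pockets, tunnels), so green tests
demonstrate correctness of the machinery and qualitative behaviors, not
agreement with any particular protein's published descriptor values.

## Problem sizes and numerical choices

Default analysis parameters are grid 200, shell 1.7 intervals, order 20,
fill fraction 0.7, MVEE tolerance 1e-4, cube edge 1.0. The test suite and
the acceptance script run scaled-down problem sizes chosen as the smallest
at which each property is stable: the ellipsoid benchmark at grid 128
(its correlation changes by <0.01 between grids 64 and 128), rotation
checks at grids 40–64, oracle equivalence at grid ≤48 and order 8.
Degenerate inputs fail loudly: coincident atoms, coplanar MVEE input,
open meshes, empty grids and saturated grids all raise (or warn, for
saturation) rather than returning junk.

## Known limitations

- The Gaussian surface is a documented substitute for rolling-probe
  surfaces; absolute `Vp`, `Vp/Vc` and genus values on real proteins can
  differ near the ±0.05 level on ratios from values computed on MSMS/
  EDTSurf-style meshes, although trends and orderings are stable.
- Absolute `F_nl` values depend on the basis normalization and unit-ball
  mapping conventions stated above; descriptor *distances* and orderings
  are the stable quantities to compare across implementations.
- Procrustes distances require index correspondence; the package never
  attempts to establish correspondence between unordered point sets.
- Sequence-level dataset culling (identity thresholds) is consumed as a
  precomputed keep-list; only the length and spatial-gap filters are
  computed here.
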