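"""PCA shape-space mapping and map-level statistics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import shapespace as ss
from shapespace.zernike import ZernikeDescriptor, invariant_count


def descriptor_cohort(n: int, order: int = 8, seed: int = 0,
                      intrinsic_dim: int = 2) -> list[ZernikeDescriptor]:
    """Random descriptors on a low-dimensional affine subspace plus noise."""
    rng = np.random.default_rng(seed)
    p = invariant_count(order)
    basis = rng.standard_normal((intrinsic_dim, p))
    spread = np.array([3.0, 1.0, 0.5])[:intrinsic_dim]
    coords = rng.standard_normal((n, intrinsic_dim)) * spread
    x = np.abs(5.0 + coords @ basis + 0.01 * rng.standard_normal((n, p)))
    return [ZernikeDescriptor(n_max=order, values=row) for row in x]


class TestFitMap:
    def test_identical_descriptors_collapse_to_origin(self):
        d = ZernikeDescriptor(n_max=4, values=np.full(invariant_count(4), 0.3))
        smap = ss.fit_map([d] * 6)
        np.testing.assert_allclose(smap.coordinates, 0.0, atol=1e-12)
        np.testing.assert_allclose(smap.eigenvalues, 0.0, atol=1e-12)

    def test_ellipsoid_series_is_essentially_low_dimensional(
            self, series_descriptors_64):
        # a one-parameter family traces a curved arc in descriptor space:
        # three components capture most, not all, of its variance (the
        # computed value at this grid size is ~0.84)
        smap = ss.fit_map(series_descriptors_64["descriptors"])
        assert smap.explained_fraction.sum() > 0.8

    def test_projection_contracts_pairwise_distances(self):
        descs = descriptor_cohort(30, seed=2)
        smap = ss.fit_map(descs)
        full = pdist(np.vstack([d.values for d in descs]))
        low = pdist(smap.coordinates)
        assert np.all(low <= full + 1e-9)

    def test_refit_is_bit_identical(self):
        descs = descriptor_cohort(25, seed=5)
        a = ss.fit_map(descs)
        b = ss.fit_map(descs)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.loadings, b.loadings)

    def test_sign_convention_largest_loading_positive(self):
        smap = ss.fit_map(descriptor_cohort(25, seed=6))
        for row in smap.loadings:
            assert row[np.argmax(np.abs(row))] >= 0

    def test_joint_fit_equals_fit_of_concatenation(self):
        a = descriptor_cohort(12, seed=7)
        b = descriptor_cohort(9, seed=8)
        joint = ss.fit_map(a + b)
        concat = ss.fit_map(list(a) + list(b))
        np.testing.assert_allclose(joint.coordinates, concat.coordinates)

    def test_too_few_or_mixed_order_rejected(self):
        descs = descriptor_cohort(3)
        with pytest.raises(ValueError, match="at least 4"):
            ss.fit_map(descs)
        mixed = descriptor_cohort(4) + [
            ZernikeDescriptor(n_max=2, values=np.ones(4))]
        with pytest.raises(ValueError, match="mixed"):
            ss.fit_map(mixed)


class TestScree:
    def test_eigenvalues_nonincreasing_and_trace_identity(self):
        descs = descriptor_cohort(30, seed=3)
        smap = ss.fit_map(descs)
        eig = ss.scree(smap, k=invariant_count(8))
        assert np.all(np.diff(eig) <= 1e-12)
        x = np.vstack([d.values for d in descs])
        total_var = np.var(x, axis=0, ddof=1).sum()
        assert eig.sum() == pytest.approx(total_var)

    def test_dominant_eigenvalue_for_one_parameter_family(
            self, series_descriptors_64):
        # the leading eigenvalue clearly dominates (about half the total
        # variance; the arc's curvature spreads the rest over later PCs)
        smap = ss.fit_map(series_descriptors_64["descriptors"])
        eig = ss.scree(smap, k=10)
        assert eig[0] > 2.5 * eig[1]
        assert eig[0] > 0.5 * eig.sum()

    def test_k_out_of_range_rejected(self):
        smap = ss.fit_map(descriptor_cohort(10))
        with pytest.raises(ValueError):
            ss.scree(smap, k=invariant_count(8) + 1)


class TestAxisProfile:
    @pytest.fixture()
    def cohort_map(self):
        return ss.fit_map(descriptor_cohort(120, seed=9, intrinsic_dim=3))

    def test_constant_values_give_constant_nonempty_bins(self, cohort_map):
        prof = ss.axis_profile(cohort_map, axis=0,
                               values=np.full(cohort_map.n_shapes, 2.5))
        filled = prof.aggregate[~np.isnan(prof.aggregate)]
        np.testing.assert_allclose(filled, 2.5)

    def test_membership_matches_brute_force_cylinder_test(self, cohort_map):
        rng = np.random.default_rng(4)
        values = rng.random(cohort_map.n_shapes)
        prof = ss.axis_profile(cohort_map, axis=1, values=values,
                               radius=2.0, height=0.5, step=0.5)
        coords = cohort_map.coordinates
        for t, agg, count in zip(prof.bin_centers, prof.aggregate, prof.counts):
            members = [i for i in range(len(coords))
                       if abs(coords[i, 1] - t) <= 0.25
                       and np.hypot(coords[i, 0], coords[i, 2]) <= 2.0]
            assert count == len(members)
            if members:
                assert agg == pytest.approx(values[members].mean())
            else:
                assert np.isnan(agg)

    def test_empty_bins_are_nan_not_zero(self, cohort_map):
        prof = ss.axis_profile(cohort_map, axis=0,
                               values=np.ones(cohort_map.n_shapes),
                               radius=0.05)
        assert np.isnan(prof.aggregate[prof.counts == 0]).all()

    def test_unknown_axis_rejected(self, cohort_map):
        with pytest.raises(ValueError, match="axis"):
            ss.axis_profile(cohort_map, axis=3,
                            values=np.ones(cohort_map.n_shapes))


class TestAxisRegression:
    def test_perfectly_linear_profile_recovered_exactly(self):
        prof = ss.AxisProfile(
            axis=0, bin_centers=np.arange(-2, 2.5, 0.5),
            aggregate=0.7 - 0.1 * np.arange(-2, 2.5, 0.5),
            counts=np.full(9, 5), shape_values=np.ones(45),
            shape_coords=np.zeros(45))
        res = ss.axis_regression(prof)
        assert res.slope == pytest.approx(-0.1)
        assert res.intercept == pytest.approx(0.7)
        assert abs(res.r) == pytest.approx(1.0)

    def test_constant_profile_has_zero_slope(self):
        prof = ss.AxisProfile(
            axis=0, bin_centers=np.arange(5.0),
            aggregate=np.full(5, 1.3), counts=np.full(5, 4),
            shape_values=np.full(20, 1.3), shape_coords=np.arange(20.0))
        res = ss.axis_regression(prof)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_per_shape_r_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(5)
        coords = rng.standard_normal(60)
        values = 0.4 * coords + 0.1 * rng.standard_normal(60)
        prof = ss.AxisProfile(
            axis=0, bin_centers=np.arange(-2, 2.5, 0.5),
            aggregate=np.linspace(0, 1, 9), counts=np.full(9, 5),
            shape_values=values, shape_coords=coords)
        res = ss.axis_regression(prof)
        x, y = coords - coords.mean(), values - values.mean()
        brute = (x @ y) / np.sqrt((x @ x) * (y @ y))
        assert res.r_per_shape == pytest.approx(brute)

    def test_too_few_bins_rejected(self):
        prof = ss.AxisProfile(
            axis=0, bin_centers=np.arange(3.0),
            aggregate=np.array([1.0, np.nan, 2.0]), counts=np.array([1, 0, 1]),
            shape_values=np.ones(2), shape_coords=np.arange(2.0))
        with pytest.raises(ValueError, match="3 nonempty"):
            ss.axis_regression(prof)


class TestCubeOccupancy:
    def test_identical_sets_fully_shared(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-5, 5, (100, 3))
        shared, only_a, only_b = ss.cube_occupancy(pts, pts.copy(), edge=1.0)
        assert (shared, only_a, only_b) == (1.0, 0.0, 0.0)

    def test_disjoint_far_clusters_share_nothing(self):
        a = np.zeros((10, 3))
        b = np.full((10, 3), 50.0)
        shared, only_a, only_b = ss.cube_occupancy(a, b, edge=1.0)
        assert shared == 0.0
        assert only_a + only_b == pytest.approx(1.0)

    def test_fractions_match_hash_set_enumeration(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(-3, 3, (200, 3))
        b = rng.uniform(-2, 4, (150, 3))
        shared, only_a, only_b = ss.cube_occupancy(a, b, edge=1.0)
        ca = {tuple(v) for v in np.floor(a).astype(int)}
        cb = {tuple(v) for v in np.floor(b).astype(int)}
        union = len(ca | cb)
        assert shared == pytest.approx(len(ca & cb) / union)
        assert only_a == pytest.approx(len(ca - cb) / union)
        assert only_b == pytest.approx(len(cb - ca) / union)
        assert shared + only_a + only_b == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ss.cube_occupancy(np.zeros((0, 3)), np.ones((5, 3)))


class TestEnrichmentTest:
    def test_balanced_table_has_zero_statistic(self):
        chi2, p = ss.enrichment_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_matches_closed_form(self):
        # Pearson statistic for (50,0;0,50) is n = 100
        chi2, _ = ss.enrichment_test([[50, 0], [0, 50]])
        assert chi2 == pytest.approx(100.0)

    def test_invariant_to_simultaneous_row_and_column_swap(self):
        table = [[12, 30], [45, 9]]
        swapped = [[9, 45], [30, 12]]
        assert ss.enrichment_test(table)[0] == pytest.approx(
            ss.enrichment_test(swapped)[0])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            ss.enrichment_test([[0, 0], [5, 5]])
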