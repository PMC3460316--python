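import math
import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from rsdiag import (ClusterFeatureExtractor, ClusterFeatureSpec, Mask,
                    cluster_mean_features, extract_clusters,
                    monte_carlo_cluster_threshold, one_sample_tmap,
                    robust_voxel_selection, threshold_and_size_filter,
                    two_sample_tmap)
from rsdiag.types import StatMap


GRID = (10, 10, 8)


def make_mask(grid=GRID):
    return Mask(np.ones(grid, bool))


def blob_map(centers_sizes_values, grid=GRID, mask=None, df=20, peaked=False):
    """Stat map with rectangular blobs of given |t| values.

    With ``peaked`` each blob gets a tiny gradient toward its centre so it
    has a unique local maximum (like a smooth t-field would).
    """
    t = np.zeros(grid)
    for (x, y, z), (dx, dy, dz), val in centers_sizes_values:
        block = np.full((dx, dy, dz), float(val))
        if peaked:
            cx, cy, cz = (dx - 1) / 2, (dy - 1) / 2, (dz - 1) / 2
            ix, iy, iz = np.ogrid[:dx, :dy, :dz]
            dist = np.abs(ix - cx) + np.abs(iy - cy) + np.abs(iz - cz)
            block = block * (1.0 - 1e-3 * dist)
        t[x:x + dx, y:y + dy, z:z + dz] = block
    return StatMap(t, df=df, contrast="fixture", mask=mask or make_mask(grid),
                   voxel_mm=3.0)


class TestTMaps:
    def test_identical_groups_give_zero(self, rng):
        vols = rng.random((4, 5, 5, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = two_sample_tmap(vols, vols.copy(), Mask(np.ones((5, 5, 4), bool)))
        np.testing.assert_allclose(sm.t, 0.0)

    def test_df_for_239_vs_429(self, rng):
        mask = Mask(np.ones((3, 3, 2), bool))
        sm = two_sample_tmap(rng.random((239, 3, 3, 2)), rng.random((429, 3, 3, 2)), mask)
        assert sm.df == 666

    def test_two_sample_closed_form(self):
        mask = Mask(np.ones((1, 1, 1), bool))
        A = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        B = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1, 1)
        sm = two_sample_tmap(A, B, mask)
        # means 2 vs 5, pooled sd 1, se = sqrt(2/3)
        expected = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        assert sm.t[0, 0, 0] == pytest.approx(expected)
        assert sm.df == 4

    def test_one_sample_closed_form(self):
        mask = Mask(np.ones((1, 1, 1), bool))
        sm = one_sample_tmap(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1), mask)
        assert sm.t[0, 0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        assert sm.df == 2

    def test_one_sample_zero_volumes_guarded(self):
        mask = Mask(np.ones((2, 2, 2), bool))
        sm = one_sample_tmap(np.zeros((3, 2, 2, 2)), mask)
        np.testing.assert_array_equal(sm.t, 0.0)

    def test_one_sample_shift_monotonicity(self, rng):
        mask = Mask(np.ones((3, 3, 2), bool))
        vols = rng.random((5, 3, 3, 2))
        t0 = one_sample_tmap(vols, mask).t
        t1 = one_sample_tmap(vols + 2.0, mask).t
        assert np.all(t1 > t0)


class TestThresholding:
    def test_63_voxel_threshold_at_3mm(self):
        # theta_cs = 1701 mm^3 at 3 mm voxels <-> 63 voxels
        small = ((0, 0, 0), (4, 4, 3), 3.0)   # 48 voxels, removed
        big = ((5, 0, 0), (4, 4, 4), 3.0)     # 64 voxels, kept
        sm = blob_map([small, big])
        out = threshold_and_size_filter(sm, theta_t=2.582, theta_cs=1701.0)
        assert np.all(out.t[0:4, 0:4, 0:3] == 0)
        assert np.all(out.t[5:9, 0:4, 0:4] == 3.0)
        # exactly 63 voxels (1701 mm^3) survives the >= comparison
        sm63 = blob_map([((0, 0, 0), (7, 3, 3), 3.0)])
        assert np.any(threshold_and_size_filter(sm63, 2.582, 1701.0).t != 0)

    def test_zero_thresholds_are_identity(self, rng):
        t = rng.standard_normal(GRID)
        sm = StatMap(t, df=10, contrast="x", mask=make_mask(), voxel_mm=3.0)
        out = threshold_and_size_filter(sm, 0.0, 0.0)
        np.testing.assert_array_equal(out.t, t)

    def test_five_vs_seventy_voxel_blobs(self):
        five = ((0, 0, 0), (5, 1, 1), 4.0)
        seventy = ((2, 2, 2), (7, 5, 2), 4.0)
        sm = blob_map([five, seventy])
        out = threshold_and_size_filter(sm, 2.582, 63 * 27.0)
        assert np.all(out.t[0:5, 0, 0] == 0)
        assert np.count_nonzero(out.t) == 70

    def test_opposite_signs_cluster_separately(self):
        t = np.zeros(GRID)
        t[0:2, 0, 0] = 5.0
        t[2:4, 0, 0] = -5.0  # adjacent but opposite sign: two 2-voxel blobs
        sm = StatMap(t, df=10, contrast="x", mask=make_mask(), voxel_mm=3.0)
        out = threshold_and_size_filter(sm, 1.0, 3 * 27.0)  # needs >= 3 voxels
        np.testing.assert_array_equal(out.t, 0.0)


class TestMonteCarloThreshold:
    def test_unsmoothed_high_threshold_returns_one(self):
        mask = Mask(np.ones((6, 6, 4), bool))
        thr = monte_carlo_cluster_threshold(mask, 0.0, theta_t=4.0, alpha=0.05,
                                            n_sim=200, seed=0)
        assert thr == 1

    def test_alpha_one_returns_one(self):
        mask = Mask(np.ones((6, 6, 4), bool))
        thr = monte_carlo_cluster_threshold(mask, 6.0, theta_t=2.0, alpha=1.0,
                                            n_sim=100, seed=0)
        assert thr == 1

    def test_smoothness_monotonicity(self):
        mask = Mask(np.ones((12, 12, 10), bool))
        thrs = {f: np.mean([monte_carlo_cluster_threshold(
            mask, f, theta_t=2.0, alpha=0.05, n_sim=150, seed=s, voxel_mm=3.0)
            for s in range(3)]) for f in (0.0, 8.0)}
        assert thrs[8.0] >= thrs[0.0]

    def test_degenerate_mask_raises(self):
        with pytest.raises(ValueError):
            monte_carlo_cluster_threshold(Mask(np.zeros((4, 4, 4), bool)),
                                          6.0, 2.0, n_sim=100)


class TestExtractClusters:
    def test_two_separated_bumps_ordered_by_mass(self):
        big = ((0, 0, 0), (3, 3, 3), 5.0)     # mass ~ 27*5 = 135
        small = ((7, 7, 5), (2, 2, 2), 4.0)   # mass ~ 8*4 = 32
        sm = blob_map([big, small], peaked=True)
        cs = extract_clusters(sm, d_min=12.0, v_min=0.0)
        assert len(cs) == 2
        # masses verified by direct summation over the blob regions
        assert cs[0].mass == pytest.approx(np.abs(sm.t[0:3, 0:3, 0:3]).sum())
        assert cs[1].mass == pytest.approx(np.abs(sm.t[7:9, 7:9, 5:7]).sum())
        assert cs[0].volume_mm3 == pytest.approx(27 * 27.0)

    def test_single_bump_contains_global_peak(self):
        t = np.zeros(GRID)
        x, y, z = np.ogrid[:10, :10, :8]
        t[:] = 5.0 * np.exp(-(((x - 5) ** 2 + (y - 5) ** 2 + (z - 4) ** 2) / 4.0))
        t[t < 1.0] = 0.0
        sm = StatMap(t, df=10, contrast="x", mask=make_mask(), voxel_mm=3.0)
        cs = extract_clusters(sm, d_min=30.0, v_min=0.0)
        assert len(cs) == 1
        assert cs[0].peak == (5, 5, 4)

    def test_n_clusters_keeps_most_massive(self):
        blobs = [((0, 0, 0), (2, 2, 2), 3.0),
                 ((4, 4, 0), (2, 2, 2), 6.0),
                 ((7, 7, 5), (2, 2, 2), 4.5)]
        sm = blob_map(blobs, peaked=True)
        cs = extract_clusters(sm, d_min=12.0, v_min=0.0, n_clusters=1)
        assert len(cs) == 1
        # the most massive blob, mass verified by direct summation
        assert cs[0].mass == pytest.approx(np.abs(sm.t[4:6, 4:6, 0:2]).sum())

    def test_v_min_discards_small_clusters(self):
        sm = blob_map([((0, 0, 0), (2, 1, 1), 5.0), ((5, 5, 5), (3, 3, 2), 5.0)],
                      peaked=True)
        cs = extract_clusters(sm, d_min=12.0, v_min=10 * 27.0)
        assert len(cs) == 1 and cs[0].n_voxels == 18

    def test_empty_map_gives_empty_set(self):
        sm = blob_map([])
        cs = extract_clusters(sm)
        assert len(cs) == 0

    def test_mass_invariant_to_sign_flip(self):
        sm = blob_map([((0, 0, 0), (3, 3, 2), 4.0)])
        flipped = sm.copy_with(-sm.t)
        a = extract_clusters(sm, d_min=6.0)
        b = extract_clusters(flipped, d_min=6.0)
        assert a[0].mass == pytest.approx(b[0].mass)


class TestClusterMeanFeatures:
    def test_matches_loop_oracle(self, rng):
        vols = rng.random((5,) + GRID)
        sm = blob_map([((1, 1, 1), (3, 2, 2), 4.0), ((6, 6, 4), (2, 2, 2), 3.0)],
                      peaked=True)
        cs = extract_clusters(sm, d_min=12.0)
        X = cluster_mean_features([vols], [cs])
        assert X.shape == (5, 2)
        for p in range(5):
            for c, cl in enumerate(cs):
                expected = np.mean([vols[p][tuple(v)] for v in cl.voxels])
                assert X[p, c] == pytest.approx(expected)

    def test_single_voxel_cluster_passes_value_through(self, rng):
        vols = rng.random((3,) + GRID)
        sm = blob_map([((4, 4, 4), (1, 1, 1), 5.0)])
        cs = extract_clusters(sm)
        X = cluster_mean_features([vols], [cs])
        np.testing.assert_allclose(X[:, 0], vols[:, 4, 4, 4])

    def test_200_features_from_10_clusters_over_20_maps(self, rng):
        # the FC_1-20 cluster configuration: 20 maps x 10 clusters each
        blobs = [((i % 4 * 2, i // 4 * 2, 0), (1, 1, 1), 3.0 + i) for i in range(10)]
        sm = blob_map(blobs)
        cs = extract_clusters(sm, d_min=0.0)
        assert len(cs) == 10
        vols = rng.random((7,) + GRID)
        X = cluster_mean_features([vols] * 20, [cs] * 20)
        assert X.shape == (7, 200)

    def test_all_empty_cluster_sets_raise(self, rng):
        from rsdiag.types import ClusterSet
        with pytest.raises(ValueError, match="no features selected"):
            cluster_mean_features([rng.random((3,) + GRID)], [ClusterSet([])])


class TestRobustSelection:
    def _random_thresholded(self, rng, frac):
        t = rng.standard_normal(GRID)
        t[rng.random(GRID) > frac] = 0.0
        return StatMap(t, df=10, contrast="x", mask=make_mask(), voxel_mm=3.0)

    def test_identical_subiterations_leave_map_unchanged(self, rng):
        base = self._random_thresholded(rng, 0.5)
        out = robust_voxel_selection([base], [[base]] * 9)
        np.testing.assert_array_equal(out[0].t, base.t)

    def test_one_empty_subiteration_empties_output(self, rng):
        base = self._random_thresholded(rng, 0.5)
        empty = base.copy_with(np.zeros(GRID))
        subs = [[base]] * 8 + [[empty]]
        out = robust_voxel_selection([base], subs)
        np.testing.assert_array_equal(out[0].t, 0.0)

    def test_matches_voxelwise_and_oracle(self, rng):
        base = self._random_thresholded(rng, 0.6)
        subs = [[self._random_thresholded(rng, 0.6)] for _ in range(9)]
        out = robust_voxel_selection([base], subs)
        survive = base.t != 0
        for s in subs:
            survive &= s[0].t != 0
        expected = np.where(survive, base.t, 0.0)
        np.testing.assert_array_equal(out[0].t, expected)
        assert np.count_nonzero(out[0].t) <= np.count_nonzero(base.t)

    def test_wrong_subiteration_count_raises(self, rng):
        base = self._random_thresholded(rng, 0.5)
        with pytest.raises(ValueError):
            robust_voxel_selection([base], [[base]] * 8)

    def test_raising_threshold_shrinks_retained_set(self, rng):
        raw = StatMap(rng.standard_normal(GRID) * 3, df=10, contrast="x",
                      mask=make_mask(), voxel_mm=3.0)
        subs_raw = [StatMap(rng.standard_normal(GRID) * 3, df=10, contrast="x",
                            mask=make_mask(), voxel_mm=3.0) for _ in range(9)]
        counts = []
        for theta in (1.0, 2.0):
            base = threshold_and_size_filter(raw, theta, 0.0)
            subs = [[threshold_and_size_filter(s, theta, 0.0)] for s in subs_raw]
            out = robust_voxel_selection([base], subs)
            counts.append(np.count_nonzero(out[0].t))
        assert counts[1] <= counts[0]


class TestClusterFeatureSpec:
    def test_parse_bracket_syntax(self):
        spec = ClusterFeatureSpec.parse("[2.582, 1701, inf, 30, 540]")
        assert spec.theta_t == 2.582 and spec.theta_cs == 1701
        assert math.isinf(spec.n_clusters)
        assert spec.d_min == 30 and spec.v_min == 540

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            ClusterFeatureSpec(-1.0, 0, math.inf, 0, 0)
        with pytest.raises(ValueError):
            ClusterFeatureSpec.parse("[1, 2, 3]")


class TestClusterFeatureExtractor:
    @pytest.fixture
    def labelled_volumes(self, rng):
        n = 20
        labels = np.array(["control"] * 10 + ["adhd-c"] * 5 + ["adhd-i"] * 5)
        V = rng.standard_normal((n, 2) + GRID)
        V[10:, :, 2:5, 2:5, 2:4] += 3.0  # strong patient effect, both k maps
        return V, labels

    def test_fit_transform_shapes(self, labelled_volumes):
        V, labels = labelled_volumes
        spec = ClusterFeatureSpec(2.582, 0.0, math.inf, 9.0, 0.0)
        ext = ClusterFeatureExtractor(spec)
        X = ext.fit_transform(V, labels)
        assert X.shape[0] == 20 and X.shape[1] == ext.n_features_

    def test_two_comparison_mode_doubles_maps(self, labelled_volumes):
        V, labels = labelled_volumes
        V = V.copy()
        V[10:15, :, 6:9, 6:9, 4:7] += 3.0  # subtype difference
        spec = ClusterFeatureSpec(2.582, 0.0, math.inf, 9.0, 0.0, n_comparisons=2)
        ext = ClusterFeatureExtractor(spec).fit(V, labels)
        assert len(ext.cluster_sets_) == 4  # eta=2 maps x 2 comparisons

    def test_robust_requires_subfolds(self, labelled_volumes):
        V, labels = labelled_volumes
        spec = ClusterFeatureSpec(2.582, 0.0, math.inf, 9.0, 0.0)
        with pytest.raises(ValueError):
            ClusterFeatureExtractor(spec, robust=True).fit(V, labels)

    def test_robust_never_grows_voxel_set(self, labelled_volumes):
        V, labels = labelled_volumes
        spec = ClusterFeatureSpec(2.582, 0.0, math.inf, 9.0, 0.0)
        plain = ClusterFeatureExtractor(spec).fit(V, labels)
        rows = np.arange(20)
        sub_folds = [np.delete(rows, [2 * j, 2 * j + 1]) for j in range(9)]
        robust = ClusterFeatureExtractor(spec, robust=True).fit(
            V, labels, sub_folds=sub_folds)
        for pm, rm in zip(plain.stat_maps_, robust.stat_maps_):
            assert set(map(tuple, np.argwhere(rm.t != 0))) <= \
                set(map(tuple, np.argwhere(pm.t != 0)))
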