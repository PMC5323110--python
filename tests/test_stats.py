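"""Voxelwise group statistics: GLM, thresholds, clusters, conjunction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rehofc.core import StatMap
from rehofc.stats import (behavior_regression, cluster_table, conjunction,
                          group_glm, logit_gm, one_sample_map,
                          partial_correlation, significant_set, t_critical,
                          voxelwise_ols)


def _covariates(rng, n):
    return pd.DataFrame({
        "age": rng.integers(54, 81, n).astype(float),
        "gender": rng.integers(0, 2, n).astype(float),
        "education": rng.integers(6, 21, n).astype(float),
    })


class TestLogitGM:
    def test_midpoint_maps_to_zero(self):
        out = logit_gm(np.full((3, 3, 3), 0.5), fwhm_mm=0.0)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_closed_form_inversion(self):
        a = np.e / (1 + np.e)
        out = logit_gm(np.full((2, 2, 2), a), fwhm_mm=0.0)
        assert np.allclose(out, 0.5, atol=1e-12)

    def test_boundary_clamped_to_finite(self):
        out = logit_gm(np.ones((2, 2, 2)), fwhm_mm=0.0)
        expected = 0.5 * np.log((1 - 1e-6) / 1e-6)  # ~6.907
        assert np.allclose(out, expected, atol=1e-9)
        assert np.isfinite(out).all()


class TestOneSample:
    def test_t_matches_hand_computation(self, rng):
        maps = [rng.standard_normal((3, 3, 3)) for _ in range(5)]
        stat, _ = one_sample_map(maps, np.ones((3, 3, 3), bool), 0.05)
        stacked = np.stack(maps)
        v = (1, 2, 0)
        vals = stacked[:, v[0], v[1], v[2]]
        expected = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert stat.values[v] == pytest.approx(expected, abs=1e-10)
        assert stat.df == 4

    def test_null_maps_yield_empty_significant_set(self, rng):
        maps = [rng.normal(0, 0.01, (5, 5, 5)) for _ in range(10)]
        _, sig = one_sample_map(maps, np.ones((5, 5, 5), bool), 0.01)
        assert sig.sum() == 0

    def test_planted_network_detected_and_positive_only(self, rng):
        mask = np.ones((6, 6, 6), bool)
        net = np.zeros((6, 6, 6), bool)
        net[2:5, 2:5, 2:5] = True
        maps = [np.where(net, 0.4, 0.0) + rng.normal(0, 0.1, (6, 6, 6))
                for _ in range(40)]
        _, sig = one_sample_map(maps, mask, 0.01)
        assert (sig & net).sum() >= 0.95 * net.sum()
        assert (sig & ~net).sum() <= 2


class TestVoxelwiseOLS:
    def test_agrees_with_statsmodels_loop(self, rng):
        """Batched per-voxel GLM vs a naive per-voxel statsmodels loop."""
        n, shape = 24, (10, 10, 10)
        v = int(np.prod(shape))
        y = rng.standard_normal((n, v))
        xf = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                              rng.normal(70, 6, n)])
        g = rng.standard_normal((n, v))
        b, se, t, df = voxelwise_ols(y, xf, col=1, x_voxel=g)
        assert df == n - 4
        for j in rng.integers(0, v, 25):
            design = np.column_stack([xf, g[:, j]])
            fit = sm.OLS(y[:, j], design).fit()
            assert b[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert se[j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert t[j] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_fixed_design_matches_loop(self, rng):
        n, v = 30, 200
        y = rng.standard_normal((n, v))
        xf = np.column_stack([np.ones(n), rng.standard_normal(n)])
        b, se, t, df = voxelwise_ols(y, xf, col=1)
        for j in (0, 57, 199):
            fit = sm.OLS(y[:, j], xf).fit()
            assert t[j] == pytest.approx(fit.tvalues[1], abs=1e-8)


class TestGroupGLM:
    def _maps(self, rng, n_per_group, delta, region, shape=(8, 8, 8), sd=0.1):
        maps, groups = [], []
        for grp, mu in (("patient", delta), ("control", 0.0)):
            for _ in range(n_per_group):
                m = rng.normal(0, sd, shape)
                m[region] += mu
                maps.append(m)
                groups.append(grp)
        return maps, np.array(groups)

    def test_planted_difference_recovered_within_ci(self, rng):
        shape = (8, 8, 8)
        region = np.zeros(shape, bool)
        region[2:6, 2:6, 2:6] = True
        maps, groups = self._maps(rng, 30, 0.3, region)
        cov = _covariates(rng, 60)
        stat = group_glm(maps, groups, cov, None, np.ones(shape, bool))
        assert stat.values[region].mean() > t_critical(0.005, stat.df)
        # estimated difference at region level
        stacked = np.stack(maps)
        est = stacked[groups == "patient"][:, region].mean() - \
            stacked[groups == "control"][:, region].mean()
        se = 0.1 * np.sqrt(2 / 30)
        assert abs(est - 0.3) < 2.5 * se

    def test_gm_covariate_absorbs_gm_driven_difference(self, rng):
        """FC differences induced only through GM shrink when GM enters."""
        shape = (6, 6, 6)
        n = 25
        maps, gms, groups = [], [], []
        for grp in ("patient", "control"):
            for _ in range(n):
                gm = rng.normal(0.7 if grp == "control" else 0.5, 0.05, shape)
                fc = 1.0 * gm + rng.normal(0, 0.05, shape)  # FC purely GM-driven
                maps.append(fc)
                gms.append(gm)
                groups.append(grp)
        groups = np.array(groups)
        cov = _covariates(rng, 2 * n)
        t_without = group_glm(maps, groups, cov, None,
                              np.ones(shape, bool)).values
        t_with = group_glm(maps, groups, cov, gms,
                           np.ones(shape, bool)).values
        assert np.abs(t_with).mean() < 0.5 * np.abs(t_without).mean()

    def test_permuted_labels_control_type_one_error(self, rng):
        shape = (6, 6, 6)
        region = np.zeros(shape, bool)
        region[1:4, 1:4, 1:4] = True
        maps, groups = self._maps(rng, 15, 0.0, region, shape=shape)
        cov = _covariates(rng, 30)
        hits = 0
        n_perm = 25
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            stat = group_glm(maps, perm, cov, None, np.ones(shape, bool))
            sig = significant_set(stat, 0.005, 20)
            hits += sig.any()
        assert hits <= max(2, 0.2 * n_perm)

    def test_collinear_design_raises_naming_problem(self, rng):
        maps = [rng.standard_normal((3, 3, 3)) for _ in range(10)]
        groups = np.array(["patient"] * 5 + ["control"] * 5)
        cov = _covariates(rng, 10)
        cov["education"] = cov["age"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            group_glm(maps, groups, cov, None, np.ones((3, 3, 3), bool))


class TestBehaviorRegression:
    def test_score_effect_recovered_and_sign_flips(self, rng):
        shape = (6, 6, 6)
        n = 40
        region = np.zeros(shape, bool)
        region[2:5, 2:5, 2:5] = True
        score = rng.standard_normal(n)
        maps = [np.where(region, 0.5 * s, 0.0) + rng.normal(0, 0.1, shape)
                for s in score]
        cov = _covariates(rng, n)
        stat = behavior_regression(maps, score, cov, np.ones(shape, bool))
        assert stat.values[region].min() > t_critical(0.05, stat.df)
        flipped = behavior_regression(maps, -score, cov, np.ones(shape, bool))
        np.testing.assert_allclose(flipped.values, -stat.values, atol=1e-8)

    def test_constant_score_errors(self, rng):
        maps = [rng.standard_normal((3, 3, 3)) for _ in range(12)]
        with pytest.raises(ValueError):
            behavior_regression(maps, np.ones(12), _covariates(rng, 12),
                                np.ones((3, 3, 3), bool))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        r, p = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_score_equal_to_covariate_gives_zero(self, rng):
        x = rng.standard_normal(25)
        c = rng.standard_normal(25)
        r, _ = partial_correlation(x, c, covariates=c)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_six_point_example_matches_residual_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 7, 5])
        c = np.array([0.5, 1.0, 0.0, 2.0, 1.5, 1.0])
        design = sm.add_constant(c)
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        r, p = partial_correlation(x, y, covariates=c)
        assert r == pytest.approx(expected, abs=1e-12)
        assert 0 <= p <= 1


class TestConjunctionAndClusters:
    def test_conjunction_disjoint_and_identical(self, rng):
        a = rng.random((4, 4, 4)) > 0.5
        assert conjunction(a, ~a).sum() == 0
        np.testing.assert_array_equal(conjunction(a, a), a)

    def test_empty_table_when_nothing_survives(self, atlas):
        stat = StatMap(values=np.zeros(atlas.grid_shape), df=50,
                       contrast="x", mask=atlas.brain_mask)
        tab = cluster_table(stat, 0.005, 74, atlas)
        assert len(tab) == 0

    def test_single_blob_extent_and_mm3(self, atlas):
        vals = np.zeros(atlas.grid_shape)
        blob = np.zeros(atlas.grid_shape, bool)
        blob[10:14, 10:16, 10:15] = True  # 120 voxels
        blob &= atlas.brain_mask
        vals[blob] = 8.0
        stat = StatMap(values=vals, df=50, contrast="x", mask=atlas.brain_mask)
        tab = cluster_table(stat, 0.005, 74, atlas)
        assert len(tab) == 1
        assert tab.loc[0, "extent_voxels"] == int(blob.sum())
        assert tab.loc[0, "extent_mm3"] == int(blob.sum()) * 27.0

    def test_corner_touching_blobs_connectivity_convention(self, atlas):
        vals = np.zeros(atlas.grid_shape)
        vals[8:10, 8:10, 8:10] = 5.0
        vals[10:12, 10:12, 10:12] = 5.0  # touches only at the (10,10,10) corner
        stat = StatMap(values=vals, df=50, contrast="x",
                       mask=np.ones(atlas.grid_shape, bool))
        tab26 = cluster_table(stat, 0.005, 1, atlas, connectivity=26)
        tab6 = cluster_table(stat, 0.005, 1, atlas, connectivity=6)
        assert len(tab26) == 1
        assert len(tab6) == 2

    def test_signs_reported_separately(self, atlas):
        vals = np.zeros(atlas.grid_shape)
        vals[atlas.regions["seed_DLPFC"]] = 6.0
        vals[atlas.regions["seed_RSC"]] = -6.0
        stat = StatMap(values=vals, df=50, contrast="x", mask=atlas.brain_mask)
        tab = cluster_table(stat, 0.005, 10, atlas)
        assert set(np.sign(tab["peak_stat"])) == {-1.0, 1.0}
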