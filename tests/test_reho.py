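"""Kendall's W, ReHo maps, normalization, smoothing, seed selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from rehofc.atlas import default_atlas
from rehofc.core import StatMap
from rehofc.reho import (kendalls_w, normalize_reho, reho_map, select_seeds,
                         smooth_map)


def kendalls_w_bruteforce(block):
    """Independent oracle: textbook rank-sum evaluation, no vectorization."""
    block = np.asarray(block, dtype=float)
    k, n = block.shape
    ranks = np.array([rankdata(row, method="ordinal") for row in block])
    s = 0.0
    rbar = k * (n + 1) / 2.0
    for t in range(n):
        s += (ranks[:, t].sum() - rbar) ** 2
    return 12.0 * s / (k ** 2 * (n ** 3 - n))


class TestKendallsW:
    def test_hand_worked_three_by_three(self):
        # rank rows (1,2,3),(1,2,3),(2,1,3): rank sums (4,5,9), S=14
        block = np.array([[1.0, 2, 3], [10, 20, 30], [5, 1, 9]])
        assert kendalls_w(block) == pytest.approx(168 / 216, abs=1e-12)

    def test_identical_series_perfectly_concordant(self, rng):
        base = rng.standard_normal(40)
        block = np.tile(base, (27, 1))
        assert kendalls_w(block) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_on_random_blocks(self, rng):
        for _ in range(120):
            k = int(rng.integers(2, 30))
            n = int(rng.integers(2, 40))
            block = rng.standard_normal((k, n))
            assert kendalls_w(block) == pytest.approx(
                kendalls_w_bruteforce(block), abs=1e-12)

    def test_invariant_to_monotone_transform_of_one_series(self, rng):
        block = rng.standard_normal((5, 25))
        w0 = kendalls_w(block)
        block[2] = np.exp(3.0 * block[2]) - 7.0
        assert kendalls_w(block) == pytest.approx(w0, abs=1e-12)

    def test_too_small_block_errors(self):
        with pytest.raises(ValueError):
            kendalls_w(np.ones((1, 10)))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(hnp.arrays(np.float64,
                      st.tuples(st.integers(2, 10), st.integers(2, 15)),
                      elements=st.integers(-1000, 1000).map(float)),
           st.floats(0.1, 5.0), st.floats(-10, 10))
    def test_bounds_and_affine_invariance(self, block, scale, shift):
        """W stays in [0, 1] and is invariant under positive affine maps
        of the whole block (rank statistics ignore scale and offset).
        Values are well separated so the map cannot collapse distinct
        values through rounding."""
        w = kendalls_w(block)
        assert 0.0 <= w <= 1.0 + 1e-12
        assert kendalls_w(scale * block + shift) == pytest.approx(w, abs=1e-12)


class TestReHoMap:
    def test_shared_series_gives_unit_map(self, series_factory, rng):
        base = rng.standard_normal(30)
        data = np.broadcast_to(base, (4, 4, 4, 30)).copy()
        rmap = reho_map(series_factory(data))
        assert np.allclose(rmap.values, 1.0, atol=1e-12)

    def test_white_noise_mean_near_one_over_k(self, series_factory, rng):
        data = rng.standard_normal((12, 12, 12, 40))
        rmap = reho_map(series_factory(data))
        interior = np.zeros((12, 12, 12), dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True  # full 27-voxel neighborhoods
        mean_w = rmap.values[interior].mean()
        se = rmap.values[interior].std() / np.sqrt(interior.sum())
        # E[W] = 1/k under independence; interior voxels share neighbors so
        # allow a generous band around the 1/27 expectation
        assert abs(mean_w - 1 / 27) < 10 * se

    def test_matches_bruteforce_on_toy_volume(self, series_factory, rng):
        data = rng.standard_normal((6, 6, 6, 15))
        mask = np.ones((6, 6, 6), dtype=bool)
        mask[0, 0, :] = False  # exercise the edge/k-count path
        rmap = reho_map(series_factory(data, mask=mask), neighborhood=27)
        for v in [(0, 1, 0), (2, 3, 4), (5, 5, 5), (1, 0, 3)]:
            neigh = []
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        x, y, zz = v[0] + dx, v[1] + dy, v[2] + dz
                        if 0 <= x < 6 and 0 <= y < 6 and 0 <= zz < 6 and mask[x, y, zz]:
                            neigh.append(data[x, y, zz])
            expected = kendalls_w_bruteforce(np.array(neigh))
            assert rmap.values[v] == pytest.approx(expected, abs=1e-12)

    def test_time_permutation_destroys_planted_homogeneity(self, series_factory, rng):
        base = rng.standard_normal(60)
        data = base + 0.3 * rng.standard_normal((8, 8, 8, 60))
        s = series_factory(data)
        w_planted = reho_map(s).values[1:-1, 1:-1, 1:-1].mean()
        perm = np.stack([data[i, j, k][rng.permutation(60)]
                         for i in range(8) for j in range(8) for k in range(8)])
        w_perm = reho_map(series_factory(perm.reshape(8, 8, 8, 60))).values[
            1:-1, 1:-1, 1:-1].mean()
        assert w_planted > 0.6
        assert w_perm < 0.1  # back to the ~1/27 baseline

    @pytest.mark.parametrize("neighborhood,count", [(7, 7), (19, 19), (27, 27)])
    def test_neighborhood_sizes(self, series_factory, rng, neighborhood, count):
        data = rng.standard_normal((5, 5, 5, 20))
        rmap = reho_map(series_factory(data), neighborhood=neighborhood)
        assert rmap.neighborhood_size == neighborhood
        # center voxel has the full neighborhood available
        neigh = [data[2 + dx, 2 + dy, 2 + dz]
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (abs(dx) + abs(dy) + abs(dz) <= 1 if neighborhood == 7
                     else abs(dx) + abs(dy) + abs(dz) <= 2 if neighborhood == 19
                     else True)]
        assert len(neigh) == count
        assert rmap.values[2, 2, 2] == pytest.approx(
            kendalls_w_bruteforce(np.array(neigh)), abs=1e-12)


class TestNormalize:
    def test_constant_map_becomes_one(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        from rehofc.reho import ReHoMap
        rmap = ReHoMap(np.full((4, 4, 4), 0.4), mask, 27, False)
        out = normalize_reho(rmap)
        assert np.allclose(out.values[mask], 1.0)

    def test_mean_exactly_one(self, rng):
        from rehofc.reho import ReHoMap
        mask = rng.random((6, 6, 6)) > 0.3
        vals = np.where(mask, rng.random((6, 6, 6)) + 0.05, 0.0)
        out = normalize_reho(ReHoMap(vals, mask, 27, False))
        assert out.in_mask_mean() == pytest.approx(1.0, abs=1e-9)
        # normalizing again changes nothing
        out2 = normalize_reho(out)
        np.testing.assert_allclose(out2.values, out.values, atol=1e-12)

    def test_zero_mean_errors(self):
        from rehofc.reho import ReHoMap
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            normalize_reho(ReHoMap(np.zeros((3, 3, 3)), mask, 27, False))


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        vals = rng.random((8, 8, 8))
        np.testing.assert_array_equal(smooth_map(vals, 0.0, 3.0), vals)

    def test_interior_impulse_preserves_sum(self):
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 10] = 1.0
        out = smooth_map(vals, 8.0, 3.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_impulse_profile_matches_gaussian_sigma(self):
        vals = np.zeros((31, 31, 31))
        vals[15, 15, 15] = 1.0
        out = smooth_map(vals, 8.0, 3.0)
        sigma = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0  # ~1.1327 voxels
        profile = out[15:20, 15, 15]
        expected = profile[0] * np.exp(-np.arange(5) ** 2 / (2 * sigma ** 2))
        np.testing.assert_allclose(profile, expected, rtol=1e-3)


class TestSeedSelection:
    def _stat_map(self, atlas, values):
        return StatMap(values=values, df=50, contrast="group",
                       mask=atlas.brain_mask)

    def test_two_disjoint_clusters_give_two_seeds(self, atlas):
        vals = np.zeros(atlas.grid_shape)
        vals[atlas.regions["seed_DLPFC"]] = 5.0
        vals[atlas.regions["seed_RSC"]] = -5.0
        seeds = select_seeds(self._stat_map(atlas, vals), 3.0, 10, atlas)
        assert sorted(s.name for s in seeds) == ["seed_DLPFC", "seed_RSC"]

    def test_single_planted_difference_gives_one_named_seed(self, atlas):
        vals = np.zeros(atlas.grid_shape)
        vals[atlas.regions["seed_DLPFC"]] = 6.0
        seeds = select_seeds(self._stat_map(atlas, vals), 3.0, 10, atlas)
        assert len(seeds) == 1
        assert seeds[0].name == "seed_DLPFC"
        assert seeds[0].size == int(atlas.regions["seed_DLPFC"].sum())

    def test_null_map_gives_empty_list(self, atlas, rng):
        vals = np.where(atlas.brain_mask, rng.normal(0, 0.5, atlas.grid_shape), 0)
        assert select_seeds(self._stat_map(atlas, vals), 4.0, 10, atlas) == []

    def test_small_clusters_filtered_by_extent(self, atlas):
        vals = np.zeros(atlas.grid_shape)
        vals[atlas.regions["seed_DLPFC"]] = 6.0
        big = int(atlas.regions["seed_DLPFC"].sum())
        assert select_seeds(self._stat_map(atlas, vals), 3.0, big + 1, atlas) == []
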