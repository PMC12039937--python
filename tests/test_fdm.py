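import numpy as np
import pytest

from fracseg.fdm import (
    DeepSupervisionConfig,
    WeightMap,
    compute_fdm,
    fdm_to_weights,
    identify_cfs,
    multiscale_weights,
    normalize_weights,
)
from fracseg.io_core import EmptyLabelError, LabelMap

from conftest import random_fragment_map


def exhaustive_fdm(frag: LabelMap, cfs: np.ndarray, units="mm") -> np.ndarray:
    """O(n^2) brute-force distance to the nearest CFS voxel (the oracle)."""
    sp = np.asarray(frag.spacing) if units == "mm" else np.ones(3)
    fg_idx = np.argwhere(frag.data > 0)
    cfs_idx = np.argwhere(cfs)
    D = np.zeros(frag.data.shape)
    for v in fg_idx:
        diffs = (cfs_idx - v) * sp
        D[tuple(v)] = np.sqrt((diffs ** 2).sum(axis=1)).min()
    return D


class TestIdentifyCfs:
    def test_single_fragment_has_no_cfs(self):
        lm = LabelMap(np.ones((4, 4, 4), dtype=np.int32), scheme="fragment")
        assert not identify_cfs(lm).any()

    def test_planar_contact_marks_both_sides(self, split_fragment_map):
        cfs = identify_cfs(split_fragment_map, connectivity=26, contact_radius_mm=1.0)
        assert cfs[1].all() and cfs[2].all()
        assert not cfs[0].any() and not cfs[3].any()
        assert cfs.sum() == 32

    def test_wide_gap_out_of_reach(self):
        d = np.zeros((12, 4, 4), dtype=np.int32)
        d[:3] = 1
        d[8:] = 2  # 5-voxel (5 mm) background gap
        lm = LabelMap(d, spacing=(1, 1, 1), scheme="fragment")
        assert not identify_cfs(lm, contact_radius_mm=1.0).any()

    def test_unknown_connectivity_rejected(self, split_fragment_map):
        with pytest.raises(ValueError):
            identify_cfs(split_fragment_map, connectivity=7)


class TestComputeFdm:
    def test_planar_case_distances(self, split_fragment_map):
        f = compute_fdm(split_fragment_map)
        np.testing.assert_allclose(f.D[1], 0.0)
        np.testing.assert_allclose(f.D[2], 0.0)
        np.testing.assert_allclose(f.D[0], 1.0)
        np.testing.assert_allclose(f.D[3], 1.0)
        assert set(np.unique(f.D_hat)) == {0.0, 1.0}

    def test_dhat_bounds_and_cfs_zero(self, rng):
        for _ in range(5):
            lm = random_fragment_map(rng)
            f = compute_fdm(lm)
            assert f.D_hat.min() >= 0 and f.D_hat.max() <= 1
            assert np.all(f.D_hat[f.cfs] == 0)
            fg = lm.data > 0
            if not f.uniform_fallback and (fg & ~f.cfs).any():
                assert f.D_hat[fg].max() == 1.0

    @pytest.mark.parametrize("units", ["mm", "voxel"])
    def test_matches_exhaustive_oracle(self, units):
        spacing = (0.83, 0.83, 0.89)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lm = random_fragment_map(rng, shape=(12, 12, 12), spacing=spacing)
            f = compute_fdm(lm, units=units)
            if f.uniform_fallback:
                continue
            oracle = exhaustive_fdm(lm, f.cfs, units=units)
            np.testing.assert_allclose(f.D, np.where(lm.data > 0, oracle, 0.0),
                                       atol=1e-6)

    def test_lipschitz_in_physical_distance(self, rng):
        lm = random_fragment_map(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.5))
        f = compute_fdm(lm)
        if f.uniform_fallback:
            pytest.skip("no CFS in this draw")
        sp = np.asarray(lm.spacing)
        fg_idx = np.argwhere(lm.data > 0)
        sub = fg_idx[rng.choice(len(fg_idx), size=min(60, len(fg_idx)), replace=False)]
        for a in sub[:20]:
            for b in sub[20:40]:
                da, db = f.D[tuple(a)], f.D[tuple(b)]
                assert abs(da - db) <= np.linalg.norm((a - b) * sp) + 1e-9

    def test_empty_foreground_rejected(self):
        lm = LabelMap(np.zeros((4, 4, 4), dtype=np.int32), scheme="fragment")
        with pytest.raises(EmptyLabelError):
            compute_fdm(lm)

    def test_empty_cfs_sets_fallback(self):
        lm = LabelMap(np.ones((4, 4, 4), dtype=np.int32), scheme="fragment")
        f = compute_fdm(lm)
        assert f.uniform_fallback
        np.testing.assert_array_equal(f.D_hat, 0.0)


class TestWeights:
    def test_background_gets_lambda_back(self, split_fragment_map):
        f = compute_fdm(split_fragment_map)
        lm = split_fragment_map
        lm2 = LabelMap(np.where(lm.data == 1, 1, 0).astype(np.int32),
                       spacing=lm.spacing, scheme="fragment")
        wm = fdm_to_weights(compute_fdm(lm2), lm2, lambda_back=0.2)
        assert np.all(wm.W[lm2.data == 0] == 0.2)

    def test_cfs_weight_near_one(self, split_fragment_map):
        f = compute_fdm(split_fragment_map)
        wm = fdm_to_weights(f, split_fragment_map, lambda_back=0.2, lambda_fdm=16.0)
        expected = 0.2 + 0.8 / (1 + np.exp(-5.0))
        np.testing.assert_allclose(wm.W[f.cfs], expected, atol=1e-12)
        assert abs(expected - 0.99465) < 1e-4

    def test_logistic_midpoint(self, split_fragment_map):
        f = compute_fdm(split_fragment_map)
        f.D_hat = np.full_like(f.D_hat, 5.0 / 16.0)
        wm = fdm_to_weights(f, split_fragment_map, lambda_back=0.2, lambda_fdm=16.0)
        fg = split_fragment_map.data > 0
        np.testing.assert_allclose(wm.W[fg], 0.6, atol=1e-12)

    def test_unnormalized_range_bound(self, rng):
        lm = random_fragment_map(rng)
        f = compute_fdm(lm)
        wm = fdm_to_weights(f, lm, lambda_back=0.2, lambda_fdm=16.0)
        hi = 0.2 + 0.8 / (1 + np.exp(-5.0))
        assert wm.W.min() >= 0.2 - 1e-12
        assert wm.W.max() <= hi + 1e-12

    def test_monotone_nonincreasing_in_dhat(self):
        dhat = np.linspace(0, 1, 101)
        w = 0.2 + 0.8 / (1 + np.exp(16.0 * dhat - 5.0))
        assert np.all(np.diff(w) <= 0)

    def test_parameter_validation(self, split_fragment_map):
        f = compute_fdm(split_fragment_map)
        with pytest.raises(ValueError):
            fdm_to_weights(f, split_fragment_map, lambda_back=0.0)
        with pytest.raises(ValueError):
            fdm_to_weights(f, split_fragment_map, lambda_fdm=-1.0)

    def test_normalization_identities(self, rng):
        toy = WeightMap(W=np.array([[[0.4]], [[1.2]]]), lambda_back=0.2, lambda_fdm=16)
        out = normalize_weights(toy)
        np.testing.assert_allclose(out.W_hat.ravel(), [0.5, 1.5])
        # uniform weights are scale-invariant
        uni = WeightMap(W=np.full((3, 3, 3), 0.7), lambda_back=0.2, lambda_fdm=16)
        np.testing.assert_allclose(normalize_weights(uni).W_hat, 1.0)
        # random map: mean exactly one
        w = WeightMap(W=rng.uniform(0.1, 2.0, size=(6, 6, 6)), lambda_back=0.2,
                      lambda_fdm=16)
        assert abs(normalize_weights(w).W_hat.mean() - 1.0) < 1e-6

    def test_fallback_yields_uniform_foreground_weights(self):
        lm = LabelMap(np.ones((4, 4, 4), dtype=np.int32), scheme="fragment")
        f = compute_fdm(lm)
        wm = normalize_weights(fdm_to_weights(f, lm), frag=lm, domain="foreground")
        np.testing.assert_allclose(wm.W_hat[lm.data > 0], 1.0)


class TestMultiscale:
    def test_lambda_halves_per_level(self):
        cfg = DeepSupervisionConfig(n_levels=4, lambda0=16.0)
        assert [cfg.lambda_at(n) for n in range(4)] == [16.0, 8.0, 4.0, 2.0]

    def test_level_weights_sum_to_one(self):
        cfg = DeepSupervisionConfig(n_levels=5)
        assert abs(sum(cfg.level_loss_weights) - 1.0) < 1e-9

    def test_labels_are_nearest_downsamples(self, rng):
        lm = random_fragment_map(rng, shape=(16, 16, 16))
        cfg = DeepSupervisionConfig(n_levels=3)
        levels = multiscale_weights(lm, cfg)
        for n, (ln, wn) in enumerate(levels):
            f = 2 ** n
            np.testing.assert_array_equal(ln.data, lm.data[::f, ::f, ::f])
            assert abs(wn.W_hat.mean() - 1.0) < 1e-6

    def test_deep_levels_more_uniform(self):
        d = np.zeros((16, 16, 16), dtype=np.int32)
        d[:8] = 1
        d[8:] = 2
        lm = LabelMap(d, spacing=(1, 1, 1), scheme="fragment")
        levels = multiscale_weights(lm, DeepSupervisionConfig(n_levels=4))
        cv = [w.W_hat.std() / w.W_hat.mean() for (_, w) in levels]
        assert cv[-1] < cv[0]

    def test_too_many_levels_rejected(self, split_fragment_map):
        with pytest.raises(ValueError):
            multiscale_weights(split_fragment_map, DeepSupervisionConfig(n_levels=4))
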