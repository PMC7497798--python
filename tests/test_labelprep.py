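"""Mask building, block features, splitting and normalization."""

import numpy as np
import pytest

from flimglia import labelprep, phantom
from flimglia.labelprep import (
    FeatureTable,
    NormStats,
    build_mask,
    drop_small_objects,
    extract_dbm_vectors,
    extract_fbm_blocks,
    normalize_features,
    split_dataset,
)
from flimglia.tcspc_io import DecayCube, FitParamMaps, PARAM_NAMES, RunConfig

import helpers


def constant_maps(shape, value=1.0, valid=None):
    grids = {n: np.full(shape, float(value)) for n in PARAM_NAMES}
    return FitParamMaps.from_dict(grids, valid=valid)


class TestBuildMask:
    def test_bimodal_image_recovered_exactly(self):
        img = np.full((10, 10), 5.0)
        img[3:7, 3:7] = 50.0
        mask = build_mask(img)
        np.testing.assert_array_equal(mask, img >= 50.0)

    def test_small_object_removed(self):
        img = np.zeros((8, 8))
        img[0, 0:3] = 10.0                       # 3-px object
        assert not build_mask(img, threshold=5.0, min_object_px=5).any()
        assert build_mask(img, threshold=5.0, min_object_px=3).sum() == 3

    def test_constant_image_needs_explicit_threshold(self):
        with pytest.raises(ValueError, match="explicit threshold"):
            build_mask(np.full((5, 5), 2.0))
        assert build_mask(np.full((5, 5), 2.0), threshold=1.0).all()

    def test_phantom_label_channel_recovers_ground_truth(self):
        # synthesize a GFP-like channel: footprints at ~10x background
        cfg = helpers.tiny_culture_config(shape=(64, 64), n_microglia=4,
                                          n_other=0)
        fov = phantom.generate_phantom(cfg, seed=8)
        rng = np.random.default_rng(0)
        channel = rng.poisson(10.0, fov.mask.shape) \
            + rng.poisson(100.0, fov.mask.shape) * fov.mask
        mask = build_mask(channel.astype(float))
        disagree = (mask != fov.mask).mean()
        assert disagree <= 0.01

    def test_drop_small_objects_strict_threshold(self):
        m = np.zeros((6, 6), dtype=bool)
        m[0, :4] = True
        assert drop_small_objects(m, 4).sum() == 4     # == threshold survives
        assert not drop_small_objects(m, 5).any()


class TestExtractFBMBlocks:
    def test_constant_maps_give_constant_features(self):
        maps = constant_maps((12, 12), 3.5)
        mask = np.zeros((12, 12), dtype=bool)
        table = extract_fbm_blocks(maps, mask, RunConfig())
        np.testing.assert_allclose(table.features, 3.5)
        assert table.feature_names == PARAM_NAMES

    def test_block_means_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        grids = {n: rng.normal(size=(10, 10)) for n in PARAM_NAMES}
        maps = FitParamMaps.from_dict(grids)
        mask = rng.random((10, 10)) > 0.5
        cfg = RunConfig(block_size=8, block_stride=1)
        table = extract_fbm_blocks(maps, mask, cfg)
        assert len(table) == 9                       # (10-8+1)^2 positions
        for row in range(len(table)):
            y0, x0 = table.y[row] - 4, table.x[row] - 4
            for j, name in enumerate(PARAM_NAMES):
                brute = grids[name][y0:y0 + 8, x0:x0 + 8].mean()
                assert table.features[row, j] == pytest.approx(brute)
            assert table.labels[row] == mask[table.y[row], table.x[row]]

    def test_full_frame_block_count(self):
        maps = constant_maps((256, 256))
        table = extract_fbm_blocks(maps, np.zeros((256, 256), bool), RunConfig())
        assert len(table) == (256 - 8 + 1) ** 2

    def test_blocks_with_mostly_invalid_pixels_dropped(self):
        valid = np.ones((10, 10), dtype=bool)
        valid[:8, :5] = False                        # left half of first block
        maps = constant_maps((10, 10), 2.0, valid=valid)
        table = extract_fbm_blocks(maps, np.zeros((10, 10), bool),
                                   RunConfig(block_size=8))
        # block at (0,0) has 24/64 valid pixels -> dropped
        keys = set(zip(table.y.tolist(), table.x.tolist()))
        assert (4, 4) not in keys
        assert (4, 5) in keys                        # 32/64 valid: kept
        assert not np.isnan(table.features).any()

    def test_chi2_ablation_flag(self):
        maps = constant_maps((12, 12))
        table = extract_fbm_blocks(maps, np.zeros((12, 12), bool), RunConfig(),
                                   include_chi2=False)
        assert "chi2" not in table.feature_names
        assert table.n_features == 6

    def test_oversized_block_rejected(self):
        maps = constant_maps((6, 6))
        with pytest.raises(ValueError):
            extract_fbm_blocks(maps, np.zeros((6, 6), bool),
                               RunConfig(block_size=8))


class TestExtractDBMVectors:
    def test_vectors_are_unit_area(self):
        rng = np.random.default_rng(0)
        cube = DecayCube(counts=rng.poisson(5, (12, 12, 16)).astype(np.int64))
        table = extract_dbm_vectors(cube, np.zeros((12, 12), bool), RunConfig())
        np.testing.assert_allclose(table.features.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_cube_gives_identical_vectors(self):
        cube = DecayCube(counts=np.tile(np.arange(1, 17), (10, 10, 1)))
        table = extract_dbm_vectors(cube, np.zeros((10, 10), bool),
                                    RunConfig(block_size=1))
        assert np.ptp(table.features, axis=0).max() < 1e-12

    def test_block_sums_match_brute_force(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(3, (6, 6, 8)).astype(np.int64)
        cube = DecayCube(counts=counts)
        cfg = RunConfig(block_size=4, block_stride=1)
        table = extract_dbm_vectors(cube, np.zeros((6, 6), bool), cfg)
        for row in range(len(table)):
            y0, x0 = table.y[row] - 2, table.x[row] - 2
            brute = counts[y0:y0 + 4, x0:x0 + 4].sum(axis=(0, 1)).astype(float)
            np.testing.assert_allclose(table.features[row],
                                       brute / brute.sum(), atol=1e-12)

    def test_zero_photon_blocks_dropped(self):
        counts = np.zeros((8, 8, 8), dtype=np.int64)
        counts[6:, 6:, :] = 2                       # only lower-right corner lit
        cube = DecayCube(counts=counts)
        table = extract_dbm_vectors(cube, np.zeros((8, 8), bool),
                                    RunConfig(block_size=4, block_stride=4))
        assert len(table) == 1

    def test_same_block_keys_as_fbm(self, culture_fovs, culture_maps):
        fov, maps = culture_fovs[0], culture_maps[0]
        cfg = RunConfig(block_stride=2)
        fbm = extract_fbm_blocks(maps, fov.mask, cfg)
        dbm = extract_dbm_vectors(fov.cube, fov.mask, cfg)
        fbm_keys = set(zip(fbm.y.tolist(), fbm.x.tolist()))
        dbm_keys = set(zip(dbm.y.tolist(), dbm.x.tolist()))
        # every FBM block (photon threshold passed) is also a DBM block
        assert fbm_keys <= dbm_keys

    def test_label_rate_tracks_mask_area(self, culture_fovs):
        fov = culture_fovs[0]
        table = extract_dbm_vectors(fov.cube, fov.mask, RunConfig())
        from flimglia.detect_eval import block_grid_view
        area = block_grid_view(fov.mask, RunConfig()).mean()
        assert abs(table.labels.mean() - area) < 0.02


class TestSplitDataset:
    def _table(self, n, p=0.5, seed=0):
        rng = np.random.default_rng(seed)
        labels = (rng.random(n) < p).astype(np.int8)
        return FeatureTable(fov=np.zeros(n), x=np.zeros(n), y=np.zeros(n),
                            features=rng.normal(size=(n, 3)), labels=labels,
                            feature_names=("a", "b", "c"))

    def test_exact_70_15_15_on_round_numbers(self):
        table = self._table(100, p=0.0)
        split = split_dataset(table, (0.7, 0.15, 0.15), seed=1)
        counts = np.bincount(split.codes, minlength=3)
        np.testing.assert_array_equal(counts, [70, 15, 15])

    def test_deterministic_under_seed(self):
        table = self._table(200)
        a = split_dataset(table, seed=5)
        b = split_dataset(table, seed=5)
        np.testing.assert_array_equal(a.codes, b.codes)
        c = split_dataset(table, seed=6)
        assert (a.codes != c.codes).any()

    def test_stratified_within_one_row_per_class(self):
        table = self._table(1000, p=0.13, seed=2)
        split = split_dataset(table, (0.7, 0.15, 0.15), seed=3)
        for cls in (0, 1):
            n_cls = (table.labels == cls).sum()
            n_train = ((table.labels == cls) & split.mask(labelprep.TRAIN)).sum()
            assert abs(n_train - 0.7 * n_cls) <= 1

    def test_too_small_class_rejected(self):
        table = self._table(10, p=0.0)
        table.labels[0] = 1                          # class 1 has 1 < 3 rows
        with pytest.raises(ValueError):
            split_dataset(table, seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._table(100), (0.5, 0.4, 0.2), seed=0)


class TestNormalizeFeatures:
    def _table(self, n=50, d=4, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=np.int8)
        labels[:3] = 1
        return FeatureTable(fov=np.zeros(n), x=np.zeros(n), y=np.zeros(n),
                            features=rng.normal(5.0 + shift, 2.0, (n, d)),
                            labels=labels,
                            feature_names=tuple("fghj"[:d]))

    def test_train_output_standardized(self):
        normed, stats = normalize_features(self._table())
        np.testing.assert_allclose(normed.features.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(normed.features.std(axis=0), 1, atol=1e-9)

    def test_apply_then_invert_identity(self):
        table = self._table()
        normed, stats = normalize_features(table)
        np.testing.assert_allclose(stats.invert(normed.features),
                                   table.features, atol=1e-9)

    def test_test_rows_scaled_with_train_stats(self):
        _, stats = normalize_features(self._table(seed=0))
        shifted = self._table(shift=3.0, seed=1)
        normed, _ = normalize_features(shifted, stats=stats)
        # train stats, not its own: the shift must survive normalization
        assert normed.features.mean() > 1.0

    def test_zero_variance_feature_centered_only(self, caplog):
        table = self._table()
        table.features[:, 2] = 7.0
        with caplog.at_level("WARNING"):
            normed, stats = normalize_features(table)
        assert stats.sd[2] == 1.0
        np.testing.assert_allclose(normed.features[:, 2], 0.0, atol=1e-12)

    def test_empty_table_rejected(self):
        empty = FeatureTable(fov=np.zeros(0), x=np.zeros(0), y=np.zeros(0),
                             features=np.zeros((0, 2)), labels=np.zeros(0),
                             feature_names=("a", "b"))
        with pytest.raises(ValueError):
            normalize_features(empty)


class TestFeatureTablePersistence:
    def test_csv_round_trip_with_sidecar(self, tmp_path):
        rng = np.random.default_rng(1)
        table = FeatureTable(
            fov=np.array(["f0"] * 5, dtype=object), x=np.arange(5),
            y=np.arange(5), features=rng.normal(size=(5, 3)),
            labels=np.array([0, 1, 0, 1, 0]), feature_names=("t1", "t2", "tm"))
        table, _ = normalize_features(table)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = FeatureTable.read_csv(path)
        np.testing.assert_allclose(back.features, table.features, atol=1e-9)
        np.testing.assert_array_equal(back.labels, table.labels)
        np.testing.assert_allclose(back.stats.mean, table.stats.mean)

    def test_nan_features_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            FeatureTable(fov=np.zeros(1), x=np.zeros(1), y=np.zeros(1),
                         features=np.array([[np.nan]]), labels=np.zeros(1),
                         feature_names=("a",))
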