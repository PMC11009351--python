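"""Channel fusion, superpixel over-segmentation, first-order features and
population-level habitat clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from habitatpet.habitats import (CHANNEL_NAMES, FEATURE_COLUMNS, FusedStack,
                                 fuse_channels, oversegment,
                                 population_cluster, preprocess_case,
                                 render_habitat_map, superpixel_features)
from habitatpet.io_preproc import ImageVolume, TumorMask
from habitatpet.phantom import PhantomSpec, generate_phantom


def _vol(data):
    return ImageVolume(np.asarray(data, float), (1, 1, 1), modality="NORMALIZED")


def _random_stack(rng, mask):
    channels = {c: np.clip(rng.uniform(0, 1, mask.shape), 0, 1)
                for c in CHANNEL_NAMES}
    composite = sum(channels[c] for c in CHANNEL_NAMES)
    return FusedStack(channels=channels, composite=composite, mask=mask)


class TestFuseChannels:
    def test_all_zero_channels_give_zero_composite(self, ball_mask):
        z = _vol(np.zeros((16, 16, 16)))
        stack = fuse_channels(z, z, z, z, ball_mask)
        assert stack.composite.max() == 0

    def test_single_unit_channel_gives_unit_composite(self, ball_mask):
        z = np.zeros((16, 16, 16))
        one = _vol(np.ones((16, 16, 16)))
        stack = fuse_channels(one, _vol(z), _vol(z), _vol(z), ball_mask)
        np.testing.assert_allclose(stack.composite[ball_mask.data], 1.0)

    def test_composite_equals_independent_sum(self, rng, ball_mask):
        ct = rng.uniform(0, 1, (16, 16, 16))
        ce = rng.uniform(0, 5, (16, 16, 16))
        suv = rng.uniform(0, 19, (16, 16, 16))
        se = rng.uniform(0, 5, (16, 16, 16))
        stack = fuse_channels(_vol(ct), _vol(ce), _vol(suv), _vol(se),
                              ball_mask, entropy_bins=32)
        expected = (ct + ce / 5 + suv / 20 + se / 5)
        np.testing.assert_allclose(stack.composite, expected, atol=1e-12)
        for c in CHANNEL_NAMES:
            assert stack.channels[c].min() >= 0
            assert stack.channels[c].max() <= 1

    def test_grid_mismatch_rejected(self, ball_mask):
        small = _vol(np.zeros((8, 8, 8)))
        big = _vol(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError, match="mismatch"):
            fuse_channels(small, big, big, big, ball_mask)


class TestOversegment:
    def test_single_superpixel_covers_mask(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, n_superpixels=1)
        assert sp.n_superpixels == 1
        np.testing.assert_array_equal(sp.labels > 0, ball_mask.data)

    def test_label_count_near_target(self):
        # ~1000-voxel phantom tumor at target size 100 -> 8..15 labels
        spec = PhantomSpec.four_habitat()
        spec = PhantomSpec(**{**spec.__dict__, "grid_shape": (24, 24, 24),
                              "tumor_radii": (7.0, 6.5, 5.4)})
        case = generate_phantom(spec, 0, seed=0)
        assert 900 <= case.mask.n_voxels <= 1100
        stack = preprocess_case(case.ct, case.pet, case.mask)
        sp = oversegment(stack, target_size=100, seed=0)
        assert 8 <= sp.n_superpixels <= 15

    def test_exact_partition_of_mask(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, seed=1)
        np.testing.assert_array_equal(sp.labels > 0, ball_mask.data)
        ids = np.unique(sp.labels[sp.labels > 0])
        np.testing.assert_array_equal(ids, np.arange(1, sp.n_superpixels + 1))

    def test_labels_are_26_connected(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, seed=2)
        for s in range(1, sp.n_superpixels + 1):
            _, n = ndimage.label(sp.labels == s, structure=np.ones((3, 3, 3)))
            assert n == 1

    def test_deterministic_given_seed(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        a = oversegment(stack, seed=3)
        b = oversegment(stack, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSuperpixelFeatures:
    def test_exactly_40_feature_columns(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, seed=0)
        df = superpixel_features(stack, sp)
        feat_cols = [c for c in df.columns
                     if c not in ("patient_id", "superpixel_id")]
        assert len(feat_cols) == 40
        assert feat_cols == FEATURE_COLUMNS
        assert np.isfinite(df[feat_cols].to_numpy()).all()

    def test_constant_superpixel_degenerate_stats_are_zero(self, ball_mask):
        channels = {c: np.full((16, 16, 16), 0.3) for c in CHANNEL_NAMES}
        stack = FusedStack(channels=channels, composite=sum(channels.values()),
                           mask=ball_mask)
        labels = np.zeros((16, 16, 16), np.int32)
        labels[ball_mask.data] = 1
        from habitatpet.habitats import SuperpixelMap
        df = superpixel_features(stack, SuperpixelMap(labels))
        for stat in ("variance", "sd", "iqr", "skewness", "kurtosis"):
            assert df[f"{stat}_ct_norm"].iloc[0] == 0.0

    def test_stats_match_straight_line_recomputation(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, seed=4)
        df = superpixel_features(stack, sp)
        s = rng.integers(1, sp.n_superpixels + 1)
        sel = sp.labels == s
        row = df[df["superpixel_id"] == s].iloc[0]
        for c in CHANNEL_NAMES:
            x = stack.channels[c][sel]
            assert row[f"mean_{c}"] == pytest.approx(x.mean())
            assert row[f"median_{c}"] == pytest.approx(np.median(x))
            assert row[f"q1_{c}"] == pytest.approx(np.percentile(x, 25))
            assert row[f"q2_{c}"] == pytest.approx(np.median(x))
            assert row[f"iqr_{c}"] == pytest.approx(
                np.percentile(x, 75) - np.percentile(x, 25))
            assert row[f"sd_{c}"] == pytest.approx(x.std())
            assert row[f"variance_{c}"] == pytest.approx(x.var())
            assert row[f"energy_{c}"] == pytest.approx((x ** 2).mean())
            assert row[f"skewness_{c}"] == pytest.approx(stats.skew(x))
            assert row[f"kurtosis_{c}"] == pytest.approx(stats.kurtosis(x))

    def test_features_invariant_to_voxel_order(self, rng, ball_mask):
        # identical multisets of intensities must give identical rows, no
        # matter where the voxels sit spatially
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, seed=5)
        df1 = superpixel_features(stack, sp)
        perm = {c: v.copy() for c, v in stack.channels.items()}
        # reflect the whole grid: every superpixel keeps its voxel multiset
        flip = FusedStack(channels={c: v[::-1].copy() for c, v in perm.items()},
                          composite=stack.composite[::-1].copy(),
                          mask=TumorMask(ball_mask.data[::-1].copy(), (1, 1, 1)))
        from habitatpet.habitats import SuperpixelMap
        sp_flip = SuperpixelMap(sp.labels[::-1].copy(), sp.patient_id)
        df2 = superpixel_features(flip, sp_flip)
        pd.testing.assert_frame_equal(df1, df2)


class TestPopulationCluster:
    def _blob_table(self, rng, centers, n_per=150):
        X = np.vstack([rng.normal(c, 1.0, (n_per, 40)) for c in centers])
        return pd.DataFrame(X, columns=FEATURE_COLUMNS)

    def test_two_separated_blobs_recovered_exactly(self, rng):
        df = self._blob_table(rng, [0.0, 10.0])
        ids = population_cluster(df, seed=0)
        assert ids.max() == 2
        truth = np.repeat([0, 1], 150)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, ids) == 1.0

    def test_duplicating_rows_keeps_assignments(self, rng):
        df = self._blob_table(rng, [0.0, 10.0], n_per=80)
        base = population_cluster(df, seed=0)
        doubled = pd.concat([df, df], ignore_index=True)
        dup = population_cluster(doubled, seed=0)
        # same partition of the unique points (labels may permute)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(base, dup[: len(df)]) == 1.0
        assert adjusted_rand_score(dup[: len(df)], dup[len(df):]) == 1.0

    def test_deterministic_given_seed(self, rng):
        df = self._blob_table(rng, [0.0, 4.0, 8.0], n_per=60)
        a = population_cluster(df, seed=7)
        b = population_cluster(df, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_few_superpixels_rejected(self, rng):
        df = self._blob_table(rng, [0.0], n_per=10)
        with pytest.raises(ValueError):
            population_cluster(df, knn=20)


class TestRenderHabitatMap:
    def test_single_superpixel_uniform_label(self, ball_mask):
        from habitatpet.habitats import SuperpixelMap
        labels = np.zeros((16, 16, 16), np.int32)
        labels[ball_mask.data] = 1
        hmap = render_habitat_map(SuperpixelMap(labels), np.array([3]))
        assert set(np.unique(hmap.data[ball_mask.data])) == {3}
        assert hmap.data[~ball_mask.data].max() == 0

    def test_habitat_voxel_counts_sum_member_superpixels(self, rng, ball_mask):
        stack = _random_stack(rng, ball_mask)
        sp = oversegment(stack, seed=6)
        ids = rng.integers(1, 4, sp.n_superpixels)
        hmap = render_habitat_map(sp, ids)
        for h in (1, 2, 3):
            expected = sum((sp.labels == s + 1).sum()
                           for s in range(sp.n_superpixels) if ids[s] == h)
            assert (hmap.data == h).sum() == expected

    def test_missing_id_rejected(self, ball_mask):
        from habitatpet.habitats import SuperpixelMap
        labels = np.zeros((16, 16, 16), np.int32)
        labels[ball_mask.data] = 1
        with pytest.raises(ValueError):
            render_habitat_map(SuperpixelMap(labels), np.array([]))


class TestPreprocessCase:
    def test_channels_in_range_on_phantom(self):
        spec = PhantomSpec.four_habitat()
        case = generate_phantom(spec, 0, seed=0)
        stack = preprocess_case(case.ct, case.pet, case.mask)
        for c in CHANNEL_NAMES:
            assert stack.channels[c].min() >= 0
            assert stack.channels[c].max() <= 1
        assert stack.composite.max() <= 4.0
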