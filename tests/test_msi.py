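"""MSI matrix construction, second-order statistics, the 92-feature vector
and conventional PET metrics."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from habitatpet.io_preproc import ImageVolume, TumorMask
from habitatpet.msi import (BORDER, OUTSIDE, MSIMatrix, add_border_label,
                            build_msi_matrix, conventional_pet_metrics,
                            extract_msi_features, msi_feature_names,
                            msi_second_order)

_OFFSETS26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]


def brute_force_msi(labeled, n_habitats):
    """Triple-loop oracle: scan every voxel's 26-neighborhood and count
    ordered label pairs, skipping border-border and outside voxels."""
    counts = np.zeros((n_habitats + 1, n_habitats + 1), np.int64)
    shape = labeled.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = labeled[z, y, x]
                if a < 0:
                    continue
                for dz, dy, dx in _OFFSETS26:
                    u = (z + dz, y + dy, x + dx)
                    if not all(0 <= u[i] < shape[i] for i in range(3)):
                        continue
                    b = labeled[u]
                    if b < 0 or (a == BORDER and b == BORDER):
                        continue
                    counts[a, b] += 1
    return counts


class TestAddBorderLabel:
    def test_single_center_voxel_has_26_border_voxels(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        hmap = np.zeros((3, 3, 3), np.int32)
        hmap[1, 1, 1] = 1
        lab = add_border_label(hmap, TumorMask(mask, (1, 1, 1)))
        assert lab[1, 1, 1] == 1
        assert (lab == BORDER).sum() == 26

    def test_border_and_tumor_disjoint(self, ball_mask):
        hmap = np.zeros(ball_mask.shape, np.int32)
        hmap[ball_mask.data] = 1
        lab = add_border_label(hmap, ball_mask)
        assert not ((lab == BORDER) & ball_mask.data).any()

    def test_matches_dilation_morphology_oracle(self, ball_mask):
        hmap = np.zeros(ball_mask.shape, np.int32)
        hmap[ball_mask.data] = 1
        lab = add_border_label(hmap, ball_mask)
        ring = ndimage.binary_dilation(ball_mask.data, np.ones((3, 3, 3))) \
            & ~ball_mask.data
        np.testing.assert_array_equal(lab == BORDER, ring)

    def test_fullgrid_mask_rejected(self):
        mask = np.ones((3, 3, 3), bool)
        hmap = np.ones((3, 3, 3), np.int32)
        with pytest.raises(ValueError, match="border"):
            add_border_label(hmap, TumorMask(mask, (1, 1, 1)))

    def test_inconsistent_labels_rejected(self, ball_mask):
        hmap = np.zeros(ball_mask.shape, np.int32)  # unlabeled inside mask
        with pytest.raises(ValueError):
            add_border_label(hmap, ball_mask)


class TestBuildMSIMatrix:
    def test_two_voxel_hand_count(self):
        labeled = np.full((1, 1, 2), OUTSIDE, np.int32)
        labeled[0, 0, 0] = 1
        labeled[0, 0, 1] = 2
        m = build_msi_matrix(labeled, 2)
        expected = np.zeros((3, 3), np.int64)
        expected[1, 2] = expected[2, 1] = 1
        np.testing.assert_array_equal(m.counts, expected)

    def test_uniform_label_touches_only_itself_and_border(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        hmap = np.where(mask, 1, 0).astype(np.int32)
        lab = add_border_label(hmap, TumorMask(mask, (1, 1, 1)))
        m = build_msi_matrix(lab, 1)
        assert m.counts[1, 1] > 0 and m.counts[0, 1] > 0
        assert m.counts[0, 0] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, 3))
        labeled = rng.integers(-1, 4, shape).astype(np.int32)
        if not (labeled >= 1).any():
            labeled.flat[0] = 1
        m = build_msi_matrix(labeled, 3)
        np.testing.assert_array_equal(m.counts, brute_force_msi(labeled, 3))

    def test_symmetry_and_unordered_total(self, rng):
        labeled = rng.integers(-1, 5, (6, 6, 6)).astype(np.int32)
        labeled.flat[0] = 1
        m = build_msi_matrix(labeled, 4)
        np.testing.assert_array_equal(m.counts, m.counts.T)
        # total = 2 x number of unordered counted pairs
        iu = np.triu_indices(5, k=1)
        unordered = m.counts[iu].sum() + m.counts.diagonal().sum() // 2
        assert m.counts.sum() == 2 * unordered


class TestSecondOrder:
    def test_uniform_2x2_hand_case(self):
        counts = np.ones((2, 2), np.int64)
        contrast, homogeneity, correlation, energy = msi_second_order(counts)
        assert contrast == pytest.approx(0.5)
        assert homogeneity == pytest.approx(0.75)
        assert energy == pytest.approx(0.25)
        assert correlation == pytest.approx(0.0)

    def test_point_mass_on_diagonal(self):
        counts = np.zeros((3, 3), np.int64)
        counts[1, 1] = 7
        with pytest.warns(UserWarning, match="degenerate"):
            contrast, homogeneity, correlation, energy = msi_second_order(counts)
        assert contrast == 0 and homogeneity == 1 and energy == 1
        assert correlation == 0

    def test_transpose_invariance(self, rng):
        counts = rng.integers(0, 9, (4, 4))
        a = msi_second_order(counts)
        b = msi_second_order(counts.T)
        assert a == pytest.approx(b)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            msi_second_order(np.zeros((3, 3), np.int64))


def _phantom_msi(seed=0, n_habitats=8):
    from habitatpet.phantom import PhantomSpec, generate_phantom
    spec = PhantomSpec(tumor_radii=(12.0, 10.0, 9.0))
    case = generate_phantom(spec, subtype=seed % 3, seed=seed)
    labeled = add_border_label(case.truth_labels.data.astype(np.int32), case.mask)
    return case, build_msi_matrix(labeled, n_habitats)


class TestExtractFeatures:
    def test_92_canonical_names_for_k8(self):
        case, m = _phantom_msi(0)
        feats = extract_msi_features(m, case.truth_labels.data, 8)
        assert len(feats) == 92
        assert list(feats) == [f"MSI{i}" for i in range(1, 93)]
        assert msi_feature_names(8) == list(feats)

    def test_feature_count_general_k(self):
        assert len(msi_feature_names(4)) == 4 + 2 * (8 + 6)

    def test_single_habitat_tumor(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        hmap = np.where(mask, 1, 0).astype(np.int32)
        lab = add_border_label(hmap, TumorMask(mask, (1, 1, 1)))
        counts = np.zeros((9, 9), np.int64)
        small = build_msi_matrix(lab, 1).counts
        counts[:2, :2] = small
        feats = extract_msi_features(MSIMatrix(counts, 8), hmap, 8)
        assert feats["MSI5"] == mask.sum()
        assert feats["MSI49"] == pytest.approx(100.0)
        for i in range(21, 49):  # all pairwise interactions empty
            assert feats[f"MSI{i}"] == 0.0

    def test_percent_volumes_sum_to_100_and_normalized_in_unit_range(self):
        case, m = _phantom_msi(1)
        feats = extract_msi_features(m, case.truth_labels.data, 8)
        pct = [feats[f"MSI{i}"] for i in range(49, 57)]
        assert sum(pct) == pytest.approx(100.0, abs=1e-6)
        for i in range(57, 93):
            assert 0.0 <= feats[f"MSI{i}"] <= 1.0

    def test_every_feature_matches_independent_recomputation(self):
        case, m = _phantom_msi(2)
        hmap = case.truth_labels.data
        feats = extract_msi_features(m, hmap, 8)
        counts = brute_force_msi(
            add_border_label(hmap.astype(np.int32), case.mask), 8)
        vols = np.array([(hmap == k).sum() for k in range(1, 9)], float)
        pairs = [(i, j) for i in range(1, 9) for j in range(i + 1, 9)]
        denom = sum(counts[k, 0] for k in range(1, 9)) \
            + sum(counts[i, j] for i, j in pairs)
        c, h, r, e = msi_second_order(counts)
        assert feats["MSI1"] == pytest.approx(c)
        assert feats["MSI2"] == pytest.approx(h)
        assert feats["MSI3"] == pytest.approx(r)
        assert feats["MSI4"] == pytest.approx(e)
        for k in range(8):
            assert feats[f"MSI{5 + k}"] == vols[k]
            assert feats[f"MSI{13 + k}"] == counts[k + 1, 0]
            assert feats[f"MSI{49 + k}"] == pytest.approx(100 * vols[k] / vols.sum())
            assert feats[f"MSI{57 + k}"] == pytest.approx(counts[k + 1, 0] / denom)
        for n, (i, j) in enumerate(pairs):
            assert feats[f"MSI{21 + n}"] == counts[i, j]
            assert feats[f"MSI{65 + n}"] == pytest.approx(counts[i, j] / denom)

    def test_habitat_relabeling_permutes_features_consistently(self):
        case, m = _phantom_msi(3)
        hmap = case.truth_labels.data
        feats = extract_msi_features(m, hmap, 8)
        perm = np.array([0, 3, 1, 4, 2, 6, 5, 8, 7])  # 1-based permutation
        hmap_p = perm[hmap]
        labeled_p = add_border_label(hmap_p.astype(np.int32), case.mask)
        feats_p = extract_msi_features(build_msi_matrix(labeled_p, 8), hmap_p, 8)
        pairs = [(i, j) for i in range(1, 9) for j in range(i + 1, 9)]
        pair_pos = {frozenset(p): n for n, p in enumerate(pairs)}
        for k in range(1, 9):
            assert feats_p[f"MSI{4 + perm[k]}"] == feats[f"MSI{4 + k}"]
            assert feats_p[f"MSI{12 + perm[k]}"] == feats[f"MSI{12 + k}"]
            assert feats_p[f"MSI{48 + perm[k]}"] == pytest.approx(
                feats[f"MSI{48 + k}"])
        for n, (i, j) in enumerate(pairs):
            n_p = pair_pos[frozenset((perm[i], perm[j]))]
            assert feats_p[f"MSI{21 + n_p}"] == feats[f"MSI{21 + n}"]
            assert feats_p[f"MSI{65 + n_p}"] == pytest.approx(
                feats[f"MSI{65 + n}"])


class TestConventionalPET:
    def test_uniform_suv_hand_case(self, ball_mask):
        n = ball_mask.n_voxels
        suv = ImageVolume(np.full((16, 16, 16), 4.0), (1, 1, 1), modality="SUV")
        pm = conventional_pet_metrics(suv, ball_mask, mtv_threshold=2.5)
        assert pm.suv_max == 4.0
        assert pm.mtv_ml == pytest.approx(n / 1000.0)
        assert pm.tlg == pytest.approx(4.0 * n / 1000.0)
        assert pm.tumor_volume_ml == pytest.approx(n / 1000.0)

    def test_threshold_above_max_gives_zero_mtv(self, ball_mask):
        suv = ImageVolume(np.full((16, 16, 16), 1.5), (1, 1, 1), modality="SUV")
        pm = conventional_pet_metrics(suv, ball_mask, mtv_threshold=2.5)
        assert pm.mtv_ml == 0.0 and pm.tlg == 0.0

    def test_mean_not_above_max_and_tlg_consistent(self, rng, ball_mask):
        suv = ImageVolume(rng.uniform(0, 12, (16, 16, 16)), (1, 1, 1),
                          modality="SUV")
        pm = conventional_pet_metrics(suv, ball_mask, mtv_threshold=2.5)
        assert pm.suv_mean <= pm.suv_max
        hot = suv.data[ball_mask.data]
        hot = hot[hot >= 2.5]
        assert pm.tlg == pytest.approx(pm.mtv_ml * hot.mean(), rel=1e-6)

    def test_relative_threshold_mode(self, rng, ball_mask):
        suv = ImageVolume(rng.uniform(0, 10, (16, 16, 16)), (1, 1, 1),
                          modality="SUV")
        pm = conventional_pet_metrics(suv, ball_mask, mtv_threshold=0.4,
                                      relative=True)
        vals = suv.data[ball_mask.data]
        assert pm.mtv_ml == pytest.approx(
            (vals >= 0.4 * vals.max()).sum() / 1000.0)
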