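"""Segmentation scores, agreement tables and mean grayscale values."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bonetunnel import (
    LabelMask,
    VoxelGrid,
    confusion,
    mean_grayscale,
    pairwise_agreement,
    segmentation_scores,
)
from bonetunnel.metrics import mean_grayscale_weighted

mask_pair = st.tuples(
    hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
    hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
)


class TestConfusion:
    def test_identity(self):
        m = np.zeros((10, 10), np.uint8)
        m[:1] = 1  # 10 foreground of 100
        assert confusion(m, m) == (10, 0, 0, 90)

    def test_full_pred_half_truth(self):
        pred = np.ones((2, 4), np.uint8)
        truth = np.zeros((2, 4), np.uint8)
        truth[0] = 1
        assert confusion(pred, truth) == (4, 4, 0, 0)

    @given(mask_pair)
    @settings(max_examples=50, deadline=None)
    def test_counts_partition_pixels(self, pair):
        p, t = pair
        assert sum(confusion(p, t)) == p.size

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))


class TestScores:
    def test_identity_gives_ones(self):
        m = np.zeros((6, 6), np.uint8)
        m[2:4, 2:4] = 1
        s = segmentation_scores(m, m)
        assert (s.precision, s.recall, s.iou, s.pixel_accuracy, s.dice) == (1, 1, 1, 1, 1)

    def test_full_pred_half_truth(self):
        pred = np.ones((4, 4), np.uint8)
        truth = np.zeros((4, 4), np.uint8)
        truth[:2] = 1
        s = segmentation_scores(pred, truth)
        assert s.precision == pytest.approx(0.5)
        assert s.recall == pytest.approx(1.0)
        assert s.iou == pytest.approx(0.5)

    def test_tp2_fp2_fn2(self):
        pred = np.array([[1, 1, 1, 1, 0, 0, 0, 0]], np.uint8)
        truth = np.array([[1, 1, 0, 0, 1, 1, 0, 0]], np.uint8)
        s = segmentation_scores(pred, truth)
        assert s.iou == pytest.approx(1 / 3)
        assert s.dice == pytest.approx(1 / 2)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        s = segmentation_scores(z, z)
        assert (s.precision, s.recall, s.iou, s.dice) == (1, 1, 1, 1)

    def test_one_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        o = np.ones((4, 4), np.uint8)
        assert segmentation_scores(z, o).precision == 0.0
        assert segmentation_scores(o, z).recall == 0.0

    @given(mask_pair)
    @settings(max_examples=100, deadline=None)
    def test_dice_bounds_iou(self, pair):
        p, t = pair
        s = segmentation_scores(p, t)
        assert s.dice >= s.iou - 1e-12
        if s.iou not in (0.0, 1.0):
            assert s.dice > s.iou

    @given(mask_pair)
    @settings(max_examples=100, deadline=None)
    def test_precision_recall_swap(self, pair):
        p, t = pair
        assert segmentation_scores(p, t).precision == pytest.approx(
            segmentation_scores(t, p).recall)

    @given(mask_pair, st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, pair, seed):
        p, t = pair
        rng = np.random.default_rng(seed)
        perm = rng.permutation(p.size)
        s1 = segmentation_scores(p, t)
        s2 = segmentation_scores(p.ravel()[perm].reshape(p.shape),
                                 t.ravel()[perm].reshape(t.shape))
        assert s1 == s2


class TestPairwiseAgreement:
    @staticmethod
    def _sets():
        a = {0: np.array([[1, 1, 1, 1, 0, 0, 0, 0]], np.uint8)}
        b = {0: np.array([[1, 1, 0, 0, 1, 1, 0, 0]], np.uint8)}
        return a, b

    def test_self_agreement_is_one(self):
        a, _ = self._sets()
        table = pairwise_agreement({"D1": a, "D2": a})
        assert np.allclose(table["D1-D2"], 1.0)

    def test_hand_built_pair(self):
        a, b = self._sets()
        table = pairwise_agreement({"DR": a, "D1": b})
        assert table.loc["mIoU", "DR-D1"] == pytest.approx(1 / 3)

    def test_three_sources_three_pairs(self):
        a, b = self._sets()
        c = {0: np.zeros((1, 8), np.uint8)}
        table = pairwise_agreement({"D1": a, "D2": b, "D3": c})
        assert table.shape[1] == 3

    def test_dr_ordering_and_pr_asymmetry(self):
        a, b = self._sets()
        pred = {0: np.array([[1, 1, 1, 0, 0, 0, 0, 0]], np.uint8)}
        table = pairwise_agreement({"D1": a, "DR": pred})
        assert list(table.columns) == ["DR-D1"]
        # DR plays the prediction role: P(DR, D1) vs R = P with roles swapped
        s = segmentation_scores(pred[0], a[0])
        assert table.loc["P", "DR-D1"] == pytest.approx(s.precision)
        assert table.loc["R", "DR-D1"] == pytest.approx(s.recall)

    def test_mismatched_slices_listed(self):
        a, _ = self._sets()
        with pytest.raises(ValueError, match="1"):
            pairwise_agreement({"D1": a, "D2": {1: a[0]}})

    def test_micro_vs_macro(self):
        # slice sizes differ in foreground; macro and micro must diverge
        a = {0: np.ones((1, 8), np.uint8), 1: np.ones((1, 8), np.uint8)}
        b = {0: np.ones((1, 8), np.uint8),
             1: np.array([[1, 0, 0, 0, 0, 0, 0, 0]], np.uint8)}
        macro = pairwise_agreement({"A": a, "B": b}, pooling="macro")
        micro = pairwise_agreement({"A": a, "B": b}, pooling="micro")
        assert macro.loc["mIoU", "A-B"] == pytest.approx((1 + 1 / 8) / 2)
        assert micro.loc["mIoU", "A-B"] == pytest.approx(9 / 16)


class TestMeanGrayscale:
    def test_uniform_intensity(self):
        grid = VoxelGrid(np.full((3, 4, 4), 100.0), spacing=1.0)
        mask = LabelMask(np.ones((3, 4, 4), np.uint8))
        _, seq = mean_grayscale(grid, mask)
        assert seq == pytest.approx(100.0)

    def test_unweighted_slice_mean(self):
        # slice A: {0, 200} fully masked -> 100; slice B: 50 -> 50; seq 75
        vol = np.zeros((2, 1, 2))
        vol[0] = [[0.0, 200.0]]
        vol[1] = [[50.0, 50.0]]
        grid = VoxelGrid(vol, spacing=1.0)
        mask = LabelMask(np.ones((2, 1, 2), np.uint8))
        per_slice, seq = mean_grayscale(grid, mask)
        assert per_slice == [100.0, 50.0]
        assert seq == pytest.approx(75.0)

    def test_empty_slices_skipped(self):
        vol = np.stack([np.full((2, 2), 10.0), np.full((2, 2), 99.0)])
        mask = np.zeros((2, 2, 2), np.uint8)
        mask[0] = 1
        per_slice, seq = mean_grayscale(VoxelGrid(vol, spacing=1.0), LabelMask(mask))
        assert per_slice == [10.0] and seq == 10.0

    def test_all_empty_mask_rejected(self):
        grid = VoxelGrid(np.ones((2, 2, 2)), spacing=1.0)
        with pytest.raises(ValueError, match="no tunnel voxels"):
            mean_grayscale(grid, LabelMask(np.zeros((2, 2, 2), np.uint8)))

    def test_weighted_variant_differs(self):
        vol = np.zeros((2, 1, 2))
        vol[0] = [[0.0, 200.0]]
        vol[1] = [[50.0, 50.0]]
        grid = VoxelGrid(vol, spacing=1.0)
        mask = np.ones((2, 1, 2), np.uint8)
        mask[1, 0, 1] = 0  # 3 voxels: 0, 200, 50
        assert mean_grayscale_weighted(grid, LabelMask(mask)) == pytest.approx(250 / 3)
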