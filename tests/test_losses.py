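"""Boundary-weighted loss stack against per-pixel double-loop oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ppaseg.losses import (EPS, LossReport, PoolingSpec, boundary_weight_map,
                           edge_loss, plain_bce_loss, plain_iou_loss,
                           seg_loss, total_loss, weighted_bce_loss,
                           weighted_iou_loss)
from ppaseg.nn import Tensor


def random_pair(rng, n=8):
    P = rng.random((n, n)).astype(np.float32)
    B = (rng.random((n, n)) > 0.5).astype(np.uint8)
    return P, B


class TestWeightMap:
    def test_all_zero_mask_gives_unit_weights(self):
        W = boundary_weight_map(np.zeros((10, 10), np.uint8))
        np.testing.assert_array_equal(W, np.ones((10, 10), np.float32))

    def test_hand_computed_center_pixel(self):
        # single centre 1 in 5x5, 3x3 window: centre avg 1/9 -> 1 + 5*8/9
        B = np.zeros((5, 5), np.uint8)
        B[2, 2] = 1
        W = boundary_weight_map(B, PoolingSpec.same_size(3))
        assert W[2, 2] == pytest.approx(1.0 + 5.0 * abs(1 / 9 - 1), abs=1e-6)
        assert W[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_exhaustive_window_oracle(self, rng):
        for k in (3, 5):
            B = (rng.random((7, 7)) > 0.5).astype(np.uint8)
            W = boundary_weight_map(B, PoolingSpec.same_size(k))
            np.testing.assert_allclose(W, oracles.weight_map(B, k),
                                       atol=1e-5)

    def test_bounds_on_random_masks(self, rng):
        for _ in range(1000):
            B = (rng.random((12, 12)) > rng.random()).astype(np.uint8)
            W = boundary_weight_map(B)
            assert W.min() >= 1.0 - 1e-6
            assert W.max() <= 6.0 + 1e-6

    def test_size_changing_pool_rejected(self):
        bad = PoolingSpec((4, 4), (1, 1), (1, 1))
        with pytest.raises(ValueError, match="H_out"):
            boundary_weight_map(np.zeros((8, 8), np.uint8), bad)

    def test_output_size_arithmetic(self):
        # floor((H + 2p - k)/s) + 1
        spec = PoolingSpec((3, 3), (2, 2), (1, 1))
        assert spec.output_size(7, 9) == (4, 5)
        assert PoolingSpec.same_size(31).output_size(352, 352) == (352, 352)


class TestOracleEquivalence:
    """Vectorised implementations vs scalar double loops, 20 random 8x8."""

    @pytest.mark.parametrize("trial", range(20))
    def test_all_losses_match_double_loop(self, trial):
        rng = np.random.default_rng(1000 + trial)
        P, B = random_pair(rng)
        W = boundary_weight_map(B, PoolingSpec.same_size(3))
        assert plain_bce_loss(P, B) == pytest.approx(
            oracles.bce_loss(P, B), abs=1e-6)
        assert edge_loss(P, B) == pytest.approx(
            oracles.bce_loss(P, B), abs=1e-6)
        assert plain_iou_loss(P, B) == pytest.approx(
            oracles.iou_loss(P, B), abs=1e-6)
        assert weighted_iou_loss(P, B, W) == pytest.approx(
            oracles.weighted_iou_loss(P, B, W), abs=1e-6)
        assert weighted_bce_loss(P, B, W) == pytest.approx(
            oracles.weighted_bce_loss(P, B, W), abs=1e-6)
        assert seg_loss(P, B, PoolingSpec.same_size(3)) == pytest.approx(
            oracles.seg_loss(P, B, kernel=3), abs=1e-6)

    def test_total_loss_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(77)
        n = 16
        G_s = (rng.random((n, n)) > 0.6).astype(np.uint8)
        G_e = (rng.random((n, n)) > 0.9).astype(np.uint8)
        outputs = {k: rng.random((n, n)).astype(np.float32)
                   for k in ("S_e", "S_g", "S_5", "S_4", "S_3")}
        pool = PoolingSpec.same_size(5)
        report = total_loss(outputs, G_s, G_e, pool=pool)
        want = oracles.bce_loss(outputs["S_e"], G_e)
        for k in ("S_g", "S_5", "S_4", "S_3"):
            want += oracles.seg_loss(outputs[k], G_s, kernel=5)
        assert report.l_total == pytest.approx(want, abs=1e-5)


class TestAnalyticValues:
    def test_bce_at_half_is_ln2(self):
        P = np.full((8, 8), 0.5, np.float32)
        B = (np.arange(64).reshape(8, 8) % 2).astype(np.uint8)
        assert plain_bce_loss(P, B) == pytest.approx(np.log(2), abs=1e-6)

    def test_perfect_prediction_losses_vanish(self, rng):
        B = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        assert weighted_iou_loss(B.astype(np.float32), B) == 0.0
        assert plain_iou_loss(B.astype(np.float32), B) == 0.0
        assert plain_bce_loss(B.astype(np.float32), B) <= 2e-6
        assert seg_loss(B.astype(np.float32), B) <= 2e-6

    def test_disjoint_prediction_iou_value(self):
        # P = 1 - B: inter = 0, loss = 1 - 1/(T+1) with T = sum W (P+B)
        B = np.zeros((6, 6), np.uint8)
        B[2:4, 2:4] = 1
        P = (1 - B).astype(np.float32)
        W = boundary_weight_map(B, PoolingSpec.same_size(3))
        T = float((W * (P + B)).sum())
        assert weighted_iou_loss(P, B, W) == pytest.approx(
            1.0 - 1.0 / (T + 1.0), abs=1e-5)

    def test_uniform_weights_reduce_to_plain_bce(self, rng):
        P, B = random_pair(rng)
        W = np.ones_like(P)
        assert weighted_bce_loss(P, B, W) == plain_bce_loss(P, B)

    def test_seg_loss_is_sum_of_components(self, rng):
        P, B = random_pair(rng)
        W = boundary_weight_map(B)
        total = seg_loss(P, B)
        assert total == pytest.approx(
            weighted_iou_loss(P, B, W) + weighted_bce_loss(P, B, W),
            abs=1e-9)

    def test_sum_reduction_scales_by_pixel_count(self, rng):
        P, B = random_pair(rng, n=4)
        assert plain_bce_loss(P, B, reduction="sum") == pytest.approx(
            16 * plain_bce_loss(P, B), rel=1e-5)


class TestExhaustiveSmallGrids:
    def test_weighted_iou_zero_iff_equal_on_2x2(self):
        # all 256 binary prediction/mask pairs
        grids = [np.array(bits, np.uint8).reshape(2, 2)
                 for bits in itertools.product((0, 1), repeat=4)]
        W = np.ones((2, 2), np.float32)
        for P in grids:
            for B in grids:
                loss = weighted_iou_loss(P.astype(np.float32), B, W)
                if np.array_equal(P, B):
                    assert loss == pytest.approx(0.0, abs=1e-7)
                else:
                    assert loss > 1e-6

    def test_seg_loss_monotone_under_pixel_corruption_3x3(self):
        # flipping one correctly-predicted pixel never decreases the loss
        pool = PoolingSpec.same_size(3)
        for bits in itertools.product((0, 1), repeat=9):
            B = np.array(bits, np.uint8).reshape(3, 3)
            base = seg_loss(B.astype(np.float32), B, pool)
            for y in range(3):
                for x in range(3):
                    P = B.astype(np.float32).copy()
                    P[y, x] = 1.0 - P[y, x]
                    assert seg_loss(P, B, pool) >= base - 1e-9


class TestDifferentiability:
    def test_gradients_finite_on_random_fixtures(self, rng):
        P, B = random_pair(rng)
        for fn in (plain_bce_loss, plain_iou_loss, weighted_bce_loss,
                   weighted_iou_loss, seg_loss):
            t = Tensor(np.clip(P, 0.01, 0.99), requires_grad=True)
            out = fn(t, B)
            out.backward()
            assert np.all(np.isfinite(t.grad)), fn.__name__
            assert np.abs(t.grad).max() > 0, fn.__name__

    def test_training_path_keeps_tensor_terms(self, rng):
        P, B = random_pair(rng, n=4)
        outputs = {k: Tensor(rng.random((1, 1, 4, 4), dtype=np.float64
                                        ).astype(np.float32),
                             requires_grad=True)
                   for k in ("S_e", "S_g", "S_5", "S_4", "S_3")}
        report = total_loss(outputs, B, B, pool=PoolingSpec.same_size(3))
        assert report.tensor is not None
        report.tensor.backward()
        for k, t in outputs.items():
            assert t.grad is not None, k


class TestValidation:
    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            plain_bce_loss(rng.random((4, 4)), np.zeros((5, 5), np.uint8))

    def test_non_binary_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            seg_loss(rng.random((4, 4)), np.full((4, 4), 0.5))

    def test_missing_side_output_rejected(self, rng):
        B = np.zeros((4, 4), np.uint8)
        with pytest.raises(ValueError, match="S_4"):
            total_loss({"S_e": B * 0.5, "S_g": B * 0.5, "S_5": B * 0.5,
                        "S_3": B * 0.5}, B, B,
                       pool=PoolingSpec.same_size(3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1))
    def test_weight_map_bounds_property(self, bits):
        B = np.array([(bits >> k) & 1 for k in range(16)],
                     np.uint8).reshape(4, 4)
        W = boundary_weight_map(B, PoolingSpec.same_size(3))
        assert W.min() >= 1.0 - 1e-6 and W.max() <= 6.0 + 1e-6
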