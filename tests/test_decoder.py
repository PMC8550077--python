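"""Edge attention, parallel partial decoder, reverse attention, assembly."""

import numpy as np
import pytest

import oracles
from ppaseg.backbones import BackboneSpec
from ppaseg.decoder import (EdgeAttention, OTUnet, PartialDecoder,
                            ReverseAttention, assemble_ot_unet,
                            reverse_attention)
from ppaseg.nn import Tensor

TINY = (8, 8, 16, 24, 32)


class TestEdgeAttention:
    def test_shape_contract(self, rng):
        ea = EdgeAttention(8, np.random.default_rng(0)).eval()
        f2 = Tensor(rng.standard_normal((1, 8, 22, 22)).astype(np.float32))
        e_att, s_e = ea(f2)
        assert e_att.shape == (1, 32, 22, 22)
        assert s_e.shape == (1, 1, 22, 22)

    def test_zero_input_gives_constant_logits(self):
        ea = EdgeAttention(4, np.random.default_rng(1)).eval()
        _, s_e = ea(Tensor(np.zeros((1, 4, 8, 8), np.float32)))
        assert np.ptp(s_e.data) < 1e-6  # bias-only output

    def test_determinism(self, rng):
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        a = EdgeAttention(4, np.random.default_rng(2)).eval()(x)[0].data
        b = EdgeAttention(4, np.random.default_rng(2)).eval()(x)[0].data
        np.testing.assert_array_equal(a, b)


class TestPartialDecoder:
    def _naive(self, pd: PartialDecoder, f3, f4, f5):
        """Compose the stated operations step by step with naive routines."""
        g3 = oracles.convbn_eval(f3, pd.r3)
        g4 = oracles.convbn_eval(f4, pd.r4)
        g5 = oracles.convbn_eval(f5, pd.r5)
        hw3, hw4 = f3.shape[1:], f4.shape[1:]
        g4p = g4 * oracles.resize_bilinear(
            oracles.convbn_eval(g5, pd.t54), *hw4)
        g3p = (g3 * oracles.resize_bilinear(
            oracles.convbn_eval(g4, pd.t43), *hw3)
            * oracles.resize_bilinear(oracles.convbn_eval(g5, pd.t53), *hw3))
        cat = np.concatenate([g3p, oracles.resize_bilinear(g4p, *hw3),
                              oracles.resize_bilinear(g5, *hw3)], axis=0)
        fused = oracles.convbn_eval(cat, pd.fuse)
        return oracles.conv_plain(fused, pd.head)

    def test_shape_contract(self, rng):
        pd = PartialDecoder(16, 24, 32, np.random.default_rng(0)).eval()
        f3 = Tensor(rng.standard_normal((1, 16, 44, 44)).astype(np.float32))
        f4 = Tensor(rng.standard_normal((1, 24, 22, 22)).astype(np.float32))
        f5 = Tensor(rng.standard_normal((1, 32, 11, 11)).astype(np.float32))
        assert pd(f3, f4, f5).shape == (1, 1, 44, 44)

    def test_zero_f5_annihilates_gated_maps(self, rng):
        # multiplicative top-down gating: zero coarse evidence zeroes g4',g3'
        pd = PartialDecoder(4, 4, 4, np.random.default_rng(1),
                            reduce=4).eval()
        # force the BN affine to the identity on the zero path
        for layer in (pd.r5, pd.t54, pd.t53, pd.t43):
            layer.bn.beta.data[...] = 0.0
        if pd.r5.conv.bias is not None:
            pd.r5.conv.bias.data[...] = 0.0
        f3 = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        f4 = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        f5 = Tensor(np.zeros((1, 4, 2, 2), np.float32))
        hw = (8, 8)
        g5 = pd.r5(f5)
        g4p = pd.r4(f4) * __import__("ppaseg.nn", fromlist=["resize_bilinear"]
                                     ).resize_bilinear(pd.t54(g5), (4, 4))
        assert np.abs(g5.data).max() < 1e-6
        assert np.abs(g4p.data).max() < 1e-6

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_straight_line_oracle(self, rng, trial):
        pd = PartialDecoder(6, 8, 10, np.random.default_rng(trial),
                            reduce=5).eval()
        f3 = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
        f4 = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        f5 = rng.standard_normal((1, 10, 2, 2)).astype(np.float32)
        got = pd(Tensor(f3), Tensor(f4), Tensor(f5)).data[0]
        want = self._naive(pd, f3[0], f4[0], f5[0])
        np.testing.assert_allclose(got, want, atol=1e-4)


class TestReverseAttention:
    def _naive(self, ra: ReverseAttention, f_i, s_higher, e_att):
        hw = f_i.shape[1:]
        s_up = oracles.resize_bilinear(s_higher, *hw)
        a_i = 1.0 - oracles.sigmoid(s_up)
        gated = oracles.conv_plain(f_i, ra.reduce) * a_i
        pooled = oracles.avg_pool(e_att, e_att.shape[1] // hw[0])
        r_i = np.concatenate([gated, pooled], axis=0)
        h = oracles.convbn_eval(r_i, ra.c1)
        h = oracles.convbn_eval(h, ra.c2)
        return r_i, oracles.conv_plain(h, ra.head) + s_up

    def test_reversal_identity_exact(self, rng):
        ra = ReverseAttention(8, np.random.default_rng(0), edge_ch=4).eval()
        f = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        s = Tensor(rng.standard_normal((1, 1, 8, 8)).astype(np.float32) * 5)
        e = Tensor(rng.standard_normal((1, 4, 16, 16)).astype(np.float32))
        _, _, a = ra(f, s, e)
        from ppaseg.nn import resize_bilinear
        s_up = resize_bilinear(s, (4, 4)).sigmoid()
        np.testing.assert_allclose(a.data + s_up.data, 1.0, atol=1e-6)

    def test_saturated_higher_map_passes_through(self, rng):
        # huge positive logits: A_i -> 0, so S_i ~= resize(S_higher) + bias
        ra = ReverseAttention(4, np.random.default_rng(3), edge_ch=4).eval()
        f = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        s = Tensor(np.full((1, 1, 8, 8), 50.0, np.float32))
        e = Tensor(np.zeros((1, 4, 8, 8), np.float32))
        _, s_i, a = ra(f, s, e)
        assert np.abs(a.data).max() < 1e-6
        bias_only = s_i.data - 50.0
        assert np.ptp(bias_only) < 1e-4  # spatially constant correction

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_unfused_oracle(self, rng, trial):
        ra = ReverseAttention(6, np.random.default_rng(trial), reduce=5,
                              edge_ch=4).eval()
        f = rng.standard_normal((1, 6, 4, 4)).astype(np.float32)
        s = rng.standard_normal((1, 1, 8, 8)).astype(np.float32)
        e = rng.standard_normal((1, 4, 16, 16)).astype(np.float32)
        r_got, s_got, _ = ra(Tensor(f), Tensor(s), Tensor(e))
        r_want, s_want = self._naive(ra, f[0], s[0], e[0])
        np.testing.assert_allclose(r_got.data[0], r_want, atol=1e-4)
        np.testing.assert_allclose(s_got.data[0], s_want, atol=1e-4)

    def test_level_validation(self, rng):
        f = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        s = rng.standard_normal((1, 1, 8, 8)).astype(np.float32)
        e = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="level"):
            reverse_attention(f, s, e, level=2)


@pytest.fixture(scope="module")
def model():
    spec = BackboneSpec(variant="resnet", channel_counts=TINY)
    return assemble_ot_unet(spec, seed=0).eval()


class TestAssembly:

    def test_side_output_grids(self, model, rng):
        out = model(rng.random((64, 64), dtype=np.float32))
        assert out["S_e"].shape == (1, 1, 16, 16)
        assert out["S_g"].shape == (1, 1, 8, 8)
        assert out["S_5"].shape == (1, 1, 2, 2)
        assert out["S_4"].shape == (1, 1, 4, 4)
        assert out["S_3"].shape == (1, 1, 8, 8)
        for k in ("S_e", "S_g", "S_5", "S_4", "S_3"):
            assert out[k + "_up"].shape == (1, 1, 64, 64)
        assert out["prob"].shape == (1, 1, 64, 64)
        assert out["prob"].data.min() >= 0 and out["prob"].data.max() <= 1

    def test_final_map_is_sigmoid_of_upsampled_s3(self, model, rng):
        out = model(rng.random((64, 64), dtype=np.float32))
        np.testing.assert_allclose(out["prob"].data,
                                   oracles.sigmoid(out["S_3_up"].data),
                                   atol=1e-6)

    def test_eval_forward_deterministic(self, model, rng):
        x = rng.random((64, 64), dtype=np.float32)
        np.testing.assert_array_equal(model(x)["prob"].data,
                                      model(x)["prob"].data)

    def test_reversal_identity_inside_full_model(self, model, rng):
        from ppaseg.nn import resize_bilinear
        out = model(rng.random((64, 64), dtype=np.float32),
                    return_attention=True)
        pairs = {5: ("S_g", (2, 2)), 4: ("S_5", (4, 4)), 3: ("S_4", (8, 8))}
        for level, (higher, hw) in pairs.items():
            s_up = resize_bilinear(out[higher], hw).sigmoid()
            np.testing.assert_allclose(
                out["A"][level].data + s_up.data, 1.0, atol=1e-6)

    def test_extreme_inputs_stay_finite(self, model, rng):
        for scale in (1e3, -1e3):
            out = model(np.full((64, 64), scale, np.float32))
            for k in ("S_e_up", "S_g_up", "S_5_up", "S_4_up", "S_3_up",
                      "prob"):
                assert np.all(np.isfinite(out[k].data)), k
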