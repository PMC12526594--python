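"""Network-level checks: published layer geometry, fusion-layer closed forms,
attention oracles, decision fusion, variants and persistence."""

import numpy as np
import pytest

from tsfnet.autograd import Tensor, no_grad
from tsfnet.network import (Cafe, Efgf, ModelConfig, TSFNet, build_model,
                            decision_fuse, efgf_forward, gap_temporal,
                            scaled_dot_attention)

EXPECTED_CONV_SHAPES = {
    "eeg_conv1": (8, 8, 100, 16),
    "eeg_conv2": (4, 4, 50, 32),
    "fnirs_conv1": (11, 8, 8, 15, 16),
    "fnirs_conv2": (11, 4, 4, 8, 32),
    "fusion_conv1": (8, 8, 100, 16),
    "fusion_conv2": (4, 4, 50, 32),
    "efgf1_conv_eeg": (8, 8, 100, 1),
    "efgf1_conv_fnirs": (11, 8, 8, 15, 1),
    "efgf2_conv_eeg": (4, 4, 50, 1),
    "efgf2_conv_fnirs": (11, 4, 4, 8, 1),
}


@pytest.fixture(scope="module")
def full_forward(rng):
    model = TSFNet(ModelConfig(seed=0)).eval()
    eeg = rng.standard_normal((2, 16, 16, 600)).astype(np.float32)
    fnirs = rng.standard_normal((2, 11, 16, 16, 30, 2)).astype(np.float32)
    with no_grad():
        result = model(eeg, fnirs)
    return model, result, eeg, fnirs


def small_config(**kw):
    base = dict(width_scale=0.25, cafe_dim=16, cafe_heads=2, head_hidden=8)
    base.update(kw)
    return ModelConfig(**base)


class TestConvStackGeometry:
    def test_all_published_feature_dimensions_reproduced(self, full_forward):
        _, result, _, _ = full_forward
        for name, expected in EXPECTED_CONV_SHAPES.items():
            assert tuple(result.conv_shapes[name]) == expected, name

    def test_post_gap_feature_blocks(self, full_forward):
        _, result, _, _ = full_forward
        n = 2
        assert result.y_eeg.shape == (n, 2)
        assert result.enhanced_fnirs.shape[:2] == (n, 11)
        assert result.enhanced_fusion.shape[:2] == (n, 16)


def test_gap_temporal_reduces_only_the_time_axis():
    x = np.arange(2 * 3 * 3 * 4 * 5, dtype=float).reshape(2, 3, 3, 4, 5)
    pooled = gap_temporal(Tensor(x))
    assert pooled.shape == (2, 3, 3, 5)
    assert np.allclose(pooled.data, x.mean(axis=3))
    const = gap_temporal(Tensor(np.full((1, 2, 2, 7, 3), 4.2)))
    assert np.allclose(const.data, 4.2)


class TestEfgfLayer:
    def _zeroed_layer(self, c=2):
        layer = Efgf(c, c, (2, 2, 2), (2, 2, 2), np.random.default_rng(0))
        layer.conv_eeg.weight.data[...] = 0
        layer.conv_eeg.bias.data[...] = 0
        layer.conv_fnirs.weight.data[...] = 0
        layer.conv_fnirs.bias.data[...] = 0
        return layer

    def test_closed_form_at_gamma_zero(self, rng):
        layer = self._zeroed_layer()
        f_eeg = Tensor(rng.standard_normal((3, 4, 4, 6, 2)))
        f_fus = Tensor(rng.standard_normal((3, 4, 4, 6, 2)))
        f_fn = Tensor(rng.standard_normal((3, 5, 4, 4, 3, 2)))
        fused, phi = efgf_forward(layer, f_eeg, f_fn, f_fus)
        assert np.allclose(phi.data, 0.5)            # sigmoid(0) everywhere
        assert np.allclose(fused.data, 1.5 * f_fus.data, atol=1e-6)

    def test_closed_form_at_gamma_one(self, rng):
        layer = self._zeroed_layer()
        layer.gamma.data = np.asarray(1.0, dtype=np.float32)
        f_eeg = Tensor(rng.standard_normal((2, 4, 4, 6, 2)))
        f_fus = Tensor(rng.standard_normal((2, 4, 4, 6, 2)))
        f_fn = Tensor(rng.standard_normal((2, 5, 4, 4, 3, 2)))
        fused, _ = efgf_forward(layer, f_eeg, f_fn, f_fus)
        assert np.allclose(fused.data, f_eeg.data + 0.5 * f_fus.data, atol=1e-6)

    def test_attention_map_stays_in_open_unit_interval(self, rng):
        layer = Efgf(2, 2, (2, 2, 2), (2, 2, 2), rng)
        for alpha in (0.0, 0.3, 1.0):
            layer.alpha.data = np.asarray(alpha, dtype=np.float32)
            _, phi = efgf_forward(
                layer,
                Tensor(rng.standard_normal((2, 4, 4, 6, 2)).astype(np.float32) * 5),
                Tensor(rng.standard_normal((2, 5, 4, 4, 3, 2)).astype(np.float32) * 5),
                Tensor(rng.standard_normal((2, 4, 4, 6, 2)).astype(np.float32)),
            )
            assert (phi.data > 0).all() and (phi.data < 1).all()

    def test_matches_scalar_loop_reference(self, rng):
        """Oracle: naive per-element loops over Eq-style EFGF arithmetic."""
        layer = Efgf(1, 1, (2, 2, 2), (2, 2, 2), rng)
        layer.gamma.data = np.asarray(0.3)
        layer.alpha.data = np.asarray(0.7)
        n, h, w, t, s, tf = 2, 2, 2, 2, 3, 2
        f_eeg = rng.standard_normal((n, h, w, t, 1))
        f_fus = rng.standard_normal((n, h, w, t, 1))
        f_fn = rng.standard_normal((n, s, h, w, tf, 1))
        fused, phi = efgf_forward(layer, Tensor(f_eeg), Tensor(f_fn), Tensor(f_fus))

        def conv_same(x, wgt, bias):
            # stride-1 same conv, one output channel; asymmetric extra
            # padding at the end of each axis, matching the adaptive rule
            k1, k2, k3 = wgt.shape[:3]
            out = np.zeros(x.shape[:-1])
            xp = np.pad(x, ((0, 0), ((k1 - 1) // 2, k1 // 2), ((k2 - 1) // 2, k2 // 2),
                            ((k3 - 1) // 2, k3 // 2), (0, 0)))
            for a in range(x.shape[1]):
                for b_ in range(x.shape[2]):
                    for c in range(x.shape[3]):
                        acc = np.zeros(x.shape[0])
                        for i in range(k1):
                            for j in range(k2):
                                for u in range(k3):
                                    acc = acc + xp[:, a + i, b_ + j, c + u, 0] * wgt[i, j, u, 0, 0]
                        out[:, a, b_, c] = acc + bias[0]
            return out

        sig = lambda v: 1 / (1 + np.exp(-v))
        a_eeg = sig(conv_same(f_eeg, layer.conv_eeg.weight.data,
                              layer.conv_eeg.bias.data).mean(axis=3))
        fn_flat = f_fn.reshape(n * s, h, w, tf, 1)
        a_fn = conv_same(fn_flat, layer.conv_fnirs.weight.data,
                         layer.conv_fnirs.bias.data).mean(axis=3)
        a_fn = sig(a_fn.reshape(n, s, h, w).mean(axis=1))
        phi_ref = 0.7 * a_fn + 0.3 * a_eeg
        fused_ref = 0.3 * f_eeg + 0.7 * f_fus + phi_ref[:, :, :, None, None] * f_fus
        assert np.allclose(phi.data, phi_ref, atol=1e-6)
        assert np.allclose(fused.data, fused_ref, atol=1e-6)


class TestScaledDotAttention:
    def test_single_key_returns_its_value(self, rng):
        q = rng.standard_normal((5, 3))
        k = rng.standard_normal((1, 3))
        v = rng.standard_normal((1, 4))
        out = scaled_dot_attention(q, k, v).data
        assert np.allclose(out, np.repeat(v, 5, axis=0))

    def test_hand_computed_two_key_example(self):
        out = scaled_dot_attention(np.array([[1.0, 0.0]]),
                                   np.array([[1.0, 0.0], [0.0, 1.0]]),
                                   np.array([[1.0, 2.0], [3.0, 4.0]])).data
        w = np.exp([1 / np.sqrt(2), 0.0]); w /= w.sum()
        assert np.allclose(out, [w @ np.array([[1., 2.], [3., 4.]])], atol=1e-3)
        assert np.allclose(out, [[1.660, 2.660]], atol=2e-3)

    def test_identical_keys_average_the_values(self, rng):
        q = rng.standard_normal((4, 3))
        k = np.tile(rng.standard_normal(3), (6, 1))
        v = rng.standard_normal((6, 2))
        assert np.allclose(scaled_dot_attention(q, k, v).data,
                           np.tile(v.mean(axis=0), (4, 1)), atol=1e-12)

    def test_matches_loop_oracle_on_small_instances(self, rng):
        for _ in range(5):
            nq, nk, dk, dv = rng.integers(1, 5, 4)
            q = rng.standard_normal((nq, dk))
            k = rng.standard_normal((nk, dk))
            v = rng.standard_normal((nk, dv))
            ref = np.zeros((nq, dv))
            for i in range(nq):
                s = np.array([q[i] @ k[j] / np.sqrt(dk) for j in range(nk)])
                e = np.exp(s - s.max()); e /= e.sum()
                ref[i] = sum(e[j] * v[j] for j in range(nk))
            assert np.allclose(scaled_dot_attention(q, k, v).data, ref, atol=1e-6)

    def test_zero_key_dim_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((1, 0)), np.zeros((1, 0)), np.zeros((1, 2)))


class TestCafeLayer:
    def test_gate_zero_bypasses_attention(self, rng):
        cafe = Cafe(fnirs_token_dim=8, fusion_token_dim=4, dim=8, heads=2, rng=rng)
        f_fn = Tensor(rng.standard_normal((3, 11, 2, 2, 2)).astype(np.float32))
        f_fus = Tensor(rng.standard_normal((3, 4, 4, 4)).astype(np.float32))
        # raw gate 0 -> sigmoid 0.5; force hard bypass with a very negative raw gate
        cafe.stream_fnirs.gate.data = np.asarray(-50.0, dtype=np.float32)
        cafe.stream_fusion.gate.data = np.asarray(-50.0, dtype=np.float32)
        enh_fn, enh_fus = cafe(f_fn, f_fus)
        proj_fn = cafe.proj_fnirs(f_fn.reshape(3, 11, -1) + cafe.pos_enc)
        proj_fus = cafe.proj_fusion(f_fus.reshape(3, -1, 4))
        assert np.allclose(enh_fn.data, proj_fn.data, atol=1e-5)
        assert np.allclose(enh_fus.data, proj_fus.data, atol=1e-5)

    def test_token_counts_and_model_dim(self, rng):
        cafe = Cafe(fnirs_token_dim=8, fusion_token_dim=4, dim=12, heads=3, rng=rng)
        enh_fn, enh_fus = cafe(Tensor(rng.standard_normal((2, 11, 2, 2, 2))),
                               Tensor(rng.standard_normal((2, 4, 4, 4))))
        assert enh_fn.shape == (2, 11, 12)
        assert enh_fus.shape == (2, 16, 12)

    def test_single_head_stream_matches_manual_attention(self, rng):
        from tsfnet.network import CrossAttentionStream
        stream = CrossAttentionStream(dim=6, heads=1, rng=rng)
        q_tok = Tensor(rng.standard_normal((1, 2, 6)))
        c_tok = Tensor(rng.standard_normal((1, 3, 6)))
        out = stream(q_tok, c_tok).data[0]
        q = q_tok.data[0] @ stream.wq.weight.data + stream.wq.bias.data
        k = c_tok.data[0] @ stream.wk.weight.data + stream.wk.bias.data
        v = c_tok.data[0] @ stream.wv.weight.data + stream.wv.bias.data
        att = scaled_dot_attention(q, k, v).data
        mixed = att @ stream.wo.weight.data + stream.wo.bias.data
        g = 1 / (1 + np.exp(-float(stream.gate.data)))
        ref = g * mixed + (1 - g) * q_tok.data[0]
        assert np.allclose(out, ref, atol=1e-6)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(cafe_dim=10, cafe_heads=4)


class TestDecisionFusion:
    def test_equal_weights_preserve_argmax(self):
        p = np.array([[0.7, 0.3]])
        fused = decision_fuse(p, p, p, np.zeros(3)).data
        assert np.allclose(fused, 0.5 * p)
        assert fused.argmax() == 0

    def test_dominant_weight_selects_branch(self):
        y1, y2, y3 = (np.array([[0.9, 0.1]]), np.array([[0.2, 0.8]]),
                      np.array([[0.45, 0.55]]))
        fused = decision_fuse(y1, y2, y3, np.array([30.0, -30.0, -30.0])).data
        assert fused.argmax() == 0

    def test_hand_computed_three_branch_example(self):
        fused = decision_fuse(np.array([[0.9, 0.1]]), np.array([[0.2, 0.8]]),
                              np.array([[0.6, 0.4]]), np.zeros(3)).data[0]
        assert np.allclose(fused, [0.283333, 0.216667], atol=1e-5)
        assert fused.argmax() == 0

    def test_weights_sum_normalization_mode(self):
        p = np.array([[0.7, 0.3]])
        fused = decision_fuse(p, p, p, np.zeros(3), mode="weights").data
        assert np.allclose(fused, p)


class TestVariants:
    def test_forward_produces_valid_simplex_scores(self, full_forward):
        _, result, _, _ = full_forward
        for y in (result.y_eeg, result.y_fnirs, result.y_fusion):
            assert np.allclose(y.data.sum(axis=1), 1, atol=1e-6)
            assert (y.data >= 0).all()
        assert (result.y_pred.data >= 0).all() and (result.y_pred.data <= 1).all()

    def test_no_cafe_has_strictly_fewer_parameters(self):
        assert build_model("no_cafe").n_parameters() < build_model("full").n_parameters()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("no_attention")

    def test_ablation_leaves_eeg_branch_untouched(self, rng):
        full = TSFNet(small_config(variant="full", seed=4)).eval()
        ablated = TSFNet(small_config(variant="no_efgf", seed=9)).eval()
        shared = dict(full.named_parameters())
        for name, p in ablated.named_parameters():
            if name.startswith(("front1", "eeg1_post", "eeg2", "head_eeg")):
                p.data = shared[name].data.copy()
        for name, buf in ablated.named_buffers():
            if name.startswith(("eeg1_post", "eeg2")):
                buf[...] = dict(full.named_buffers())[name]
        eeg = rng.standard_normal((2, 16, 16, 600)).astype(np.float32)
        fnirs = rng.standard_normal((2, 11, 16, 16, 30, 2)).astype(np.float32)
        with no_grad():
            ya = full(eeg, fnirs).y_eeg.data
            yb = ablated(eeg, fnirs).y_eeg.data
        assert np.allclose(ya, yb, atol=1e-6)

    def test_gradients_reach_every_parameter(self, rng):
        from tsfnet.losses import total_loss
        model = TSFNet(small_config(seed=2))
        model.train()
        # the published zero-initialization puts the fusion gates exactly on
        # the boundary where one attention conv is multiplied by alpha = 0;
        # connectivity is checked at mid-range gates
        model.efgf1.alpha.data = np.asarray(0.5, dtype=np.float32)
        model.efgf2.alpha.data = np.asarray(0.5, dtype=np.float32)
        eeg = rng.standard_normal((4, 16, 16, 600)).astype(np.float32)
        fnirs = rng.standard_normal((4, 11, 16, 16, 30, 2)).astype(np.float32)
        labels = np.array([0, 1, 0, 1])
        loss, bd = total_loss(model(eeg, fnirs), labels)
        assert bd.L_total > 0
        loss.backward()
        dead = [n for n, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_batch_permutation_consistency(self, rng):
        model = TSFNet(small_config(seed=5)).eval()
        eeg = rng.standard_normal((4, 16, 16, 600)).astype(np.float32)
        fnirs = rng.standard_normal((4, 11, 16, 16, 30, 2)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])
        with no_grad():
            straight = model(eeg, fnirs).y_pred.data
            permuted = model(eeg[perm], fnirs[perm]).y_pred.data
        assert np.allclose(straight[perm], permuted, atol=1e-6)

    def test_windows_path_equals_per_sample_path_in_eval(self, tiny_samples, rng):
        model = TSFNet(small_config(seed=8)).eval()
        idx = np.arange(12)
        eeg = tiny_samples.eeg_batch(idx)
        with no_grad():
            canonical = model(eeg, tiny_samples.fnirs_batch(idx)).y_pred.data
            windows, seg_map = tiny_samples.fnirs_unique_windows(idx)
            dedup = model.forward_windows(Tensor(eeg), Tensor(windows), seg_map).y_pred.data
        assert np.allclose(canonical, dedup, atol=1e-6)

    def test_checkpoint_roundtrip_preserves_outputs(self, rng, tmp_path):
        model = TSFNet(small_config(seed=6)).eval()
        eeg = rng.standard_normal((2, 16, 16, 600)).astype(np.float32)
        fnirs = rng.standard_normal((2, 11, 16, 16, 30, 2)).astype(np.float32)
        with no_grad():
            ref = model(eeg, fnirs).y_pred.data
        model.save_checkpoint(tmp_path / "ckpt")
        back = TSFNet.load_checkpoint(tmp_path / "ckpt").eval()
        with no_grad():
            out = back(eeg, fnirs).y_pred.data
        assert np.array_equal(ref, out)


class TestClassifierHead:
    def test_zero_parameters_give_uniform_probabilities(self, rng):
        from tsfnet.network import Head
        head = Head(6, 4, rng)
        for p in head.parameters():
            p.data[...] = 0
        out = head(Tensor(rng.standard_normal((3, 6)))).data
        assert np.allclose(out, 0.5)

    def test_softmax_of_known_logits(self):
        from tsfnet.autograd import softmax
        probs = softmax(Tensor(np.array([[np.log(3.0), 0.0]])), axis=-1).data
        assert np.allclose(probs, [[0.75, 0.25]], atol=1e-9)
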