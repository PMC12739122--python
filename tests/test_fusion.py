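"""Cross-modal fusion: projections, attention, gating and the classifier head."""

import numpy as np
import pytest

from beatfusion._tensor import Tensor
from beatfusion.fusion import (
    FusionClassifier,
    FusionConfig,
    FusionParameters,
    classify,
    cross_modal_attention,
    gated_fusion,
    project_features,
)


def random_params(rng, d_c, d_b, d):
    return FusionParameters(
        W_c=rng.normal(size=(d_c, d)), b_c=rng.normal(size=d),
        W_b=rng.normal(size=(d_b, d)), b_b=rng.normal(size=d),
        W_Q=rng.normal(size=(d, d)), W_K=rng.normal(size=(d, d)), W_V=rng.normal(size=(d, d)),
        W_g=rng.normal(size=(2 * d, d)), b_g=rng.normal(size=d),
    )


def attention_oracle(Cp, Bp, params, config):
    """Per-head explicit loop: softmax((C'W_Q)(B'W_K)^T/sqrt(d_k)) (B'W_V)."""
    q, k, v = Cp @ params.W_Q, Bp @ params.W_K, Bp @ params.W_V
    d_k = config.d_k
    out = np.zeros((Cp.shape[0], config.d))
    for h in range(config.h):
        sl = slice(h * d_k, (h + 1) * d_k)
        for i in range(Cp.shape[0]):
            logits = np.array([q[i, sl] @ k[j, sl] / np.sqrt(d_k) for j in range(Bp.shape[0])])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            out[i, sl] = sum(w[j] * v[j, sl] for j in range(Bp.shape[0]))
    return out


class TestProjection:
    def test_identity_projection(self, rng):
        d = 5
        C, B = rng.normal(size=(4, d)), rng.normal(size=(4, d))
        p = random_params(rng, d, d, d)
        p.W_c, p.b_c = np.eye(d), np.zeros(d)
        Cp, _ = project_features(C, B, p)
        np.testing.assert_array_equal(Cp, C)

    def test_linearity_without_bias(self, rng):
        p = random_params(rng, 3, 4, 5)
        p.b_c, p.b_b = np.zeros(5), np.zeros(5)
        C, B = rng.normal(size=(6, 3)), rng.normal(size=(6, 4))
        Cp1, Bp1 = project_features(2.5 * C, 2.5 * B, p)
        Cp2, Bp2 = project_features(C, B, p)
        np.testing.assert_allclose(Cp1, 2.5 * Cp2, atol=1e-12)
        np.testing.assert_allclose(Bp1, 2.5 * Bp2, atol=1e-12)

    def test_matches_affine_oracle(self, rng):
        p = random_params(rng, 3, 4, 5)
        C, B = rng.normal(size=(6, 3)), rng.normal(size=(6, 4))
        Cp, Bp = project_features(C, B, p)
        np.testing.assert_allclose(Cp, C @ p.W_c + p.b_c, atol=1e-9)
        np.testing.assert_allclose(Bp, B @ p.W_b + p.b_b, atol=1e-9)

    def test_dim_mismatch_rejected(self, rng):
        p = random_params(rng, 3, 4, 5)
        with pytest.raises(ValueError):
            project_features(rng.normal(size=(6, 7)), rng.normal(size=(6, 4)), p)


class TestCrossModalAttention:
    def test_single_time_step_returns_projected_value(self, rng):
        config = FusionConfig(d_c=3, d_b=4, d=6, h=2)
        p = random_params(rng, 3, 4, 6)
        Cp, Bp = rng.normal(size=(1, 6)), rng.normal(size=(1, 6))
        out = cross_modal_attention(Cp, Bp, p, config)
        np.testing.assert_allclose(out, Bp @ p.W_V, atol=1e-12)

    def test_matches_per_head_loop_oracle(self, rng):
        for _ in range(100):
            h = int(rng.choice([1, 2, 4]))
            d = int(h * rng.integers(1, 4))
            config = FusionConfig(d_c=3, d_b=5, d=d, h=h)
            p = random_params(rng, 3, 5, d)
            T = int(rng.integers(1, 6))
            Cp, Bp = rng.normal(size=(T, d)), rng.normal(size=(T, d))
            np.testing.assert_allclose(
                cross_modal_attention(Cp, Bp, p, config), attention_oracle(Cp, Bp, p, config), atol=1e-6
            )

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(d_c=3, d_b=4, d=6, h=4)


class TestGatedFusion:
    def test_saturated_gate_selects_cnn_stream(self, rng):
        d = 4
        p = random_params(rng, d, d, d)
        p.W_g, p.b_g = np.zeros((2 * d, d)), np.full(d, 30.0)
        Cp, F_cb = rng.normal(size=(5, d)), rng.normal(size=(5, d))
        np.testing.assert_allclose(gated_fusion(Cp, F_cb, p), Cp, atol=1e-9)

    def test_neutral_gate_averages(self, rng):
        d = 4
        p = random_params(rng, d, d, d)
        p.W_g, p.b_g = np.zeros((2 * d, d)), np.zeros(d)
        Cp, F_cb = rng.normal(size=(5, d)), rng.normal(size=(5, d))
        np.testing.assert_allclose(gated_fusion(Cp, F_cb, p), (Cp + F_cb) / 2, atol=1e-12)

    def test_equal_streams_are_a_fixed_point(self, rng):
        d = 4
        p = random_params(rng, d, d, d)
        Cp = rng.normal(size=(5, d))
        np.testing.assert_allclose(gated_fusion(Cp, Cp.copy(), p), Cp, atol=1e-12)

    def test_output_elementwise_between_inputs(self, rng):
        d = 6
        for _ in range(20):
            p = random_params(rng, d, d, d)
            Cp, F_cb = rng.normal(size=(7, d)), rng.normal(size=(7, d))
            F = gated_fusion(Cp, F_cb, p)
            lo, hi = np.minimum(Cp, F_cb), np.maximum(Cp, F_cb)
            assert np.all(F >= lo - 1e-12) and np.all(F <= hi + 1e-12)


class TestClassify:
    def test_probabilities_sum_to_one(self, rng):
        W, b = rng.normal(size=(10, 5)), rng.normal(size=5)
        p = classify(rng.normal(size=(4, 6)), rng.normal(size=4), (W, b))
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_weights_give_uniform(self, rng):
        p = classify(rng.normal(size=(4, 6)), rng.normal(size=4), (np.zeros((10, 5)), np.zeros(5)))
        np.testing.assert_allclose(p, 0.2, atol=1e-12)

    def test_argmax_invariant_under_logit_shift(self, rng):
        W, b = rng.normal(size=(10, 5)), rng.normal(size=5)
        F, s = rng.normal(size=(4, 6)), rng.normal(size=4)
        base = classify(F, s, (W, b))
        shifted = classify(F, s, (W, b + 7.5))
        assert base.argmax() == shifted.argmax()


class TestFusionClassifier:
    def extract_params(self, mod: FusionClassifier) -> FusionParameters:
        return FusionParameters(
            W_c=mod.proj_c.weight.data, b_c=mod.proj_c.bias.data,
            W_b=mod.proj_b.weight.data, b_b=mod.proj_b.bias.data,
            W_Q=mod.w_q.weight.data, W_K=mod.w_k.weight.data, W_V=mod.w_v.weight.data,
            W_g=mod.gate.weight.data, b_g=mod.gate.bias.data,
        )

    def test_trainable_fuse_matches_reference_pipeline(self, rng):
        config = FusionConfig(d_c=5, d_b=7, d=8, h=2)
        mod = FusionClassifier(config, d_summary=6, n_classes=4, rng=rng)
        p = self.extract_params(mod)
        C, B = rng.normal(size=(1, 9, 5)), rng.normal(size=(1, 9, 7))
        fused = mod.fuse(Tensor(C), Tensor(B)).data[0]
        Cp, Bp = project_features(C[0], B[0], p)
        expected = gated_fusion(Cp, cross_modal_attention(Cp, Bp, p, config), p)
        np.testing.assert_allclose(fused, expected, atol=1e-9)

    def test_forward_probabilities_and_gradient_reach_all_maps(self, rng):
        config = FusionConfig(d_c=5, d_b=7, d=8, h=2)
        mod = FusionClassifier(config, d_summary=6, n_classes=4, rng=rng)
        C = Tensor(rng.normal(size=(3, 9, 5)), requires_grad=True)
        B = Tensor(rng.normal(size=(3, 9, 7)), requires_grad=True)
        probs = mod.forward(C, B, Tensor(rng.normal(size=(3, 6))))
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-9)
        (probs[:, 0].log().sum() * -1.0).backward()
        for name, p in mod.parameters().items():
            assert p.grad is not None and np.abs(p.grad).max() > 0, f"dead parameter {name}"
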