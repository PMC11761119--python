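"""Architecture contracts: configuration invariants, shapes, fusion and
attention semantics, determinism, gradient flow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainqc.model import (
    FusedSwinClassifier, ModelConfig, build_model, build_swin_baseline,
    count_parameters, normalize_batch,
)
from grainqc.nn import Tensor, cross_entropy


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig.tiny(), seed=0)


class TestModelConfig:
    @pytest.mark.parametrize("bad", [
        dict(fusion_dim=256),
        dict(conv_expanded_dim=512),
        dict(depths=(2, 2)),
        dict(num_classes=1),
        dict(variant="huge"),
        dict(img_size=200),
    ])
    def test_invalid_configs_listed(self, bad):
        cfg = ModelConfig(**bad)
        with pytest.raises(ValueError, match="invalid ModelConfig"):
            cfg.validate()

    def test_default_satisfies_invariants(self):
        cfg = ModelConfig()
        cfg.validate()
        assert cfg.fusion_dim == cfg.embed_dim * 4 == 384
        assert cfg.conv_expanded_dim == 3 * cfg.fusion_dim == 1152
        assert cfg.stage_dims() == [96, 192, 384]
        assert cfg.stage_resolutions() == [56, 28, 14]


class TestArchitecture:
    def test_truncation(self, tiny_model):
        cfg = ModelConfig()
        m = build_model(cfg, seed=0)
        assert len(m.backbone.stages) == 3  # no stage 4
        assert len(m.backbone.stages[2]) == 4  # four blocks in stage 3
        assert not hasattr(m.backbone, "stage4")

    def test_fewer_parameters_than_untruncated(self):
        truncated = build_model(ModelConfig(), seed=0)
        full = build_swin_baseline(seed=0)
        assert count_parameters(truncated) < count_parameters(full)

    def test_tiny_stage_shapes(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(2, 64, 64, 3)).astype(np.float32)
        feats = tiny_model.backbone_forward(x)
        assert [tuple(f.shape) for f in feats] == [
            (2, 16, 16, 24), (2, 8, 8, 48), (2, 4, 4, 96)]

    def test_pool_heads_unify_dimension(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(2, 64, 64, 3)).astype(np.float32)
        feats = tiny_model.backbone_forward(x)
        for head, f in zip(tiny_model.pool_heads, feats):
            assert tuple(head(f).shape) == (2, 96)

    def test_deterministic_build(self):
        a = build_model(ModelConfig.tiny(), seed=5)
        b = build_model(ModelConfig.tiny(), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestFusion:
    def test_slots_preserved_exactly(self, tiny_model):
        rng = np.random.default_rng(1)
        vecs = [Tensor(rng.normal(size=(2, 96)).astype(np.float32)) for _ in range(3)]
        f4 = tiny_model.fuse(vecs)
        assert tuple(f4.shape) == (2, 3, 96)
        for i, v in enumerate(vecs):
            np.testing.assert_array_equal(f4.data[:, i, :], v.data)

    def test_repeated_vector_fills_slots(self, tiny_model):
        v = Tensor(np.ones((1, 96), dtype=np.float32) * 3.5)
        f4 = tiny_model.fuse([v, v, v])
        assert (f4.data == 3.5).all()

    def test_residual_add_identities(self):
        a = np.random.default_rng(0).normal(size=(1, 3, 96)).astype(np.float32)
        ta, tz = Tensor(a), Tensor(np.zeros_like(a))
        np.testing.assert_array_equal((ta + tz).data, a)  # additive identity
        np.testing.assert_array_equal((ta + (-ta)).data, np.zeros_like(a))
        np.testing.assert_array_equal((ta + tz).data, (tz + ta).data)

    def test_conv_module_channel_schedule(self, tiny_model):
        pooled = Tensor(np.random.default_rng(0).normal(size=(2, 96)).astype(np.float32))
        out, trace = tiny_model.conv_module(pooled)
        assert trace["reduced"] == (2, 32)
        assert trace["upsampled"] == (2, 4, 4, 32)
        assert trace["gap"] == (2, 64)
        assert trace["expanded"] == (2, 288)
        assert tuple(out.shape) == (2, 3, 96)


class TestFeatureAttention:
    def test_softmax_weight_oracle(self):
        # direct evaluation of exp(z_i)/sum_j exp(z_j)
        z = Tensor(np.array([[1.0, 2.0, 3.0]], dtype=np.float32))
        w = z.softmax(axis=-1).data[0]
        np.testing.assert_allclose(w, [0.0900, 0.2447, 0.6652], atol=5e-4)

    def test_weights_rescale_slots(self, tiny_model):
        f6 = Tensor(np.random.default_rng(2).normal(size=(3, 3, 96)).astype(np.float32))
        w, f7 = tiny_model.attention(f6)
        assert tuple(w.shape) == (3, 3)
        for i in range(3):
            np.testing.assert_allclose(
                f7.data[:, i, :], f6.data[:, i, :] * w.data[:, i : i + 1], atol=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=9, max_size=9))
    def test_weights_on_simplex_for_arbitrary_inputs(self, tiny_model, vals):
        f6 = Tensor(np.array(vals, dtype=np.float32).reshape(1, 3, 3).repeat(32, axis=2))
        w, _ = tiny_model.attention(f6)
        assert (w.data >= 0).all()
        np.testing.assert_allclose(w.data.sum(axis=1), 1.0, atol=1e-6)

    def test_nonfinite_input_rejected_by_softmax_range(self, tiny_model):
        f6 = Tensor(np.full((1, 3, 96), np.nan, dtype=np.float32))
        w, _ = tiny_model.attention(f6)
        assert np.isnan(w.data).any()  # propagates, caller guards


class TestClassifier:
    def test_zero_head_gives_uniform_probabilities(self, tiny_model):
        saved = tiny_model.head.weight.data.copy()
        tiny_model.head.weight.data[...] = 0.0
        tiny_model.head.bias.data[...] = 0.0
        x = np.random.default_rng(0).normal(size=(2, 64, 64, 3)).astype(np.float32)
        tiny_model.eval()
        probs, _ = tiny_model.forward(x)
        np.testing.assert_allclose(probs.data, 1 / 3, atol=1e-6)
        tiny_model.head.weight.data[...] = saved

    def test_probabilities_normalized(self, tiny_model):
        x = np.random.default_rng(3).normal(size=(4, 64, 64, 3)).astype(np.float32)
        tiny_model.eval()
        probs, _ = tiny_model.forward(x)
        assert (probs.data >= 0).all()
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance(self):
        z = np.random.default_rng(0).normal(size=(4, 3)).astype(np.float32)
        a = Tensor(z).softmax(axis=-1).data.argmax(1)
        b = Tensor(z + 7.0).softmax(axis=-1).data.argmax(1)
        np.testing.assert_array_equal(a, b)


class TestForward:
    def test_eval_forward_deterministic(self, tiny_model):
        x = np.random.default_rng(4).normal(size=(3, 64, 64, 3)).astype(np.float32)
        tiny_model.eval()
        p1, _ = tiny_model.forward(x)
        p2, _ = tiny_model.forward(x)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_batch_permutation_equivariance(self, tiny_model):
        imgs = (np.random.default_rng(5).random((6, 64, 64, 3)) * 255).astype(np.uint8)
        perm = np.array([3, 1, 5, 0, 4, 2])
        p = tiny_model.predict_proba(imgs)
        pp_ = tiny_model.predict_proba(imgs[perm])
        np.testing.assert_allclose(pp_, p[perm], atol=1e-6)

    def test_intermediates_collected(self, tiny_model):
        x = np.random.default_rng(6).normal(size=(1, 64, 64, 3)).astype(np.float32)
        tiny_model.eval()
        _, inter = tiny_model.forward(x, collect=True)
        assert inter["F4"] == inter["F5"] == inter["F6"] == inter["F7"] == (1, 3, 96)
        assert inter["weights"].shape == (1, 3)

    def test_gradient_reaches_every_parameter(self):
        model = build_model(ModelConfig.tiny(), seed=2)
        model.train()
        x = np.random.default_rng(7).normal(size=(8, 64, 64, 3)).astype(np.float32)
        y = np.random.default_rng(8).integers(0, 3, 8)
        logits, _ = model.logits(x)
        loss = cross_entropy(logits, y)
        loss.backward()
        dead = [p for p in model.parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []


def test_normalize_batch_range():
    imgs = np.array([[[[0, 128, 255]]]], dtype=np.uint8)
    out = normalize_batch(imgs)
    np.testing.assert_allclose(out[0, 0, 0], [-1.0, 0.00392157, 1.0], atol=1e-6)
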