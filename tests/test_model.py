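"""Attention pooling (the MIL symmetry contracts), backbones, checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admil_cyto import (ADMILModel, BackboneSpec, attention_pool, build_model,
                        classify_bag, mean_pool)
from admil_cyto.model import BACKBONE_NAMES, Checkpoint, get_state, set_state


def _random_H(rng, K, L=6):
    return rng.standard_normal((K, L))


class TestAttentionPool:
    def test_singleton_bag_passes_through(self, rng):
        H = _random_H(rng, 1)
        V, w = rng.standard_normal((3, 6)), rng.standard_normal(3)
        z, a = attention_pool(H, V, w)
        assert a.tolist() == [1.0]
        assert np.allclose(z, H[0])

    def test_identical_instances_share_weight_equally(self, rng):
        h = rng.standard_normal(6)
        H = np.tile(h, (5, 1))
        z, a = attention_pool(H, rng.standard_normal((3, 6)), rng.standard_normal(3))
        assert np.allclose(a, 0.2)
        assert np.allclose(z, h)

    def test_zero_scoring_vector_reduces_to_mean_pool(self, rng):
        H = _random_H(rng, 7)
        z, a = attention_pool(H, rng.standard_normal((3, 6)), np.zeros(3))
        assert np.allclose(a, 1 / 7)
        assert np.allclose(z, mean_pool(H))

    def test_hand_evaluated_two_instance_example(self):
        """V=[[1,0]], w=[1], h1=(0,0), h2=(10,0): logits (0, tanh 10)."""
        H = np.array([[0.0, 0.0], [10.0, 0.0]])
        z, a = attention_pool(H, np.array([[1.0, 0.0]]), np.array([1.0]))
        t = np.tanh(10.0)
        expect_a = np.exp([0.0, t]) / np.exp([0.0, t]).sum()
        assert np.allclose(a, expect_a, atol=1e-9)
        assert a[1] == pytest.approx(0.7311, abs=2e-4)
        assert np.allclose(z, a[1] * H[1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6), st.integers(1, 12))
    def test_weights_normalise_and_z_stays_in_convex_hull(self, seed, K):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((K, 5)) * 3
        z, a = attention_pool(H, rng.standard_normal((4, 5)), rng.standard_normal(4))
        assert a.sum() == pytest.approx(1.0, abs=1e-6)
        assert (a > 0).all()
        assert (z >= H.min(axis=0) - 1e-9).all() and (z <= H.max(axis=0) + 1e-9).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((6, 5))
        V, w = rng.standard_normal((4, 5)), rng.standard_normal(4)
        perm = rng.permutation(6)
        z1, a1 = attention_pool(H, V, w)
        z2, a2 = attention_pool(H[perm], V, w)
        assert np.allclose(z1, z2, atol=1e-9)
        assert np.allclose(a1[perm], a2, atol=1e-9)

    def test_empty_bag_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            attention_pool(np.zeros((0, 5)), np.zeros((3, 5)), np.zeros(3))
        with pytest.raises(ValueError):
            mean_pool(np.zeros((0, 5)))


class TestMeanPool:
    def test_simple_average(self):
        assert np.allclose(mean_pool(np.array([[1.0, 3.0], [3.0, 5.0]])), [2.0, 4.0])


class TestClassifyBag:
    def test_zero_head_is_maximally_uncertain(self):
        assert classify_bag(np.ones(4), np.zeros(4), 0.0) == pytest.approx(0.5)

    def test_sigmoid_saturates(self):
        assert classify_bag(np.ones(2), np.full(2, 50.0), 0.0) == pytest.approx(1.0)

    def test_hand_evaluated_logit(self):
        p = classify_bag(np.array([2.0, 1.0]), np.array([1.0, -1.0]), 0.0)
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)


class TestBackbones:
    @pytest.mark.parametrize("name", BACKBONE_NAMES)
    def test_feature_vector_has_configured_length(self, name, rng):
        spec = BackboneSpec(name, input_size=64, feature_dim=24)
        m = ADMILModel(spec, D=6, seed=0)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        H = m.backbone.forward(x)
        assert H.shape == (2, 24)

    def test_lenet_reference_feature_dim_is_500(self, rng):
        m = ADMILModel(BackboneSpec("lenet_like"), seed=0)
        H = m.backbone.forward(rng.random((1, 3, 64, 64)).astype(np.float32))
        assert H.shape == (1, 500)

    def test_zero_image_maps_to_zero_features(self, rng):
        # biases initialise to zero, so zeros propagate through conv/ReLU/pool
        m = ADMILModel(BackboneSpec("lenet_like", feature_dim=16), D=4, seed=0)
        H = m.backbone.forward(np.zeros((1, 3, 64, 64), np.float32))
        assert np.allclose(H, 0.0)

    def test_forward_is_deterministic_in_eval(self, rng):
        m = ADMILModel(BackboneSpec("lenet_like", feature_dim=16), D=4, seed=0)
        x = rng.random((3, 3, 64, 64)).astype(np.float32)
        p1, a1, _ = m.forward_bag(x)
        p2, a2, _ = m.forward_bag(x)
        assert p1 == p2 and np.array_equal(a1, a2)

    def test_bag_probability_is_permutation_invariant(self, rng):
        m = ADMILModel(BackboneSpec("lenet_like", feature_dim=16), D=4, seed=1)
        x = rng.random((5, 3, 64, 64)).astype(np.float32)
        perm = rng.permutation(5)
        p1, a1, _ = m.forward_bag(x)
        p2, a2, _ = m.forward_bag(x[perm])
        assert p1 == pytest.approx(p2, abs=1e-6)
        assert np.allclose(a1[perm], a2, atol=1e-6)

    def test_size_mismatch_is_an_input_error(self, rng):
        m = ADMILModel(BackboneSpec("lenet_like", input_size=64, feature_dim=16),
                       D=4, seed=0)
        with pytest.raises(ValueError, match="input size"):
            m.forward_bag(rng.random((2, 3, 96, 96)).astype(np.float32))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            BackboneSpec("vgg_like")


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, rng, tmp_path):
        m = ADMILModel(BackboneSpec("lenet_like", feature_dim=16), D=4, seed=2)
        x = rng.random((3, 3, 64, 64)).astype(np.float32)
        p0, _, _ = m.forward_bag(x)
        ck = Checkpoint(regime="admil", backbone="lenet_like", input_size=64,
                        feature_dim=16, attention_dim=4, patch_size=64,
                        state=get_state(m))
        ck.save(tmp_path / "m.npz")
        m2 = Checkpoint.load(tmp_path / "m.npz").build()
        p1, _, _ = m2.forward_bag(x)
        assert p0 == pytest.approx(p1, abs=1e-7)
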