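import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmfcount import cnn_classifier as cnn
from pmfcount.cnn_classifier import (
    ArchitectureConfig,
    NeuronParams,
    TrainingConfig,
    build_classifier,
    get_preset,
    load_model,
    neuron_response,
    predict_proba,
    save_model,
    softmax,
    train,
)
from pmfcount.errors import ConfigurationError, ValidationError


class TestNeuronResponse:
    def test_relu_at_zero(self):
        assert neuron_response([1, 1], NeuronParams([1, 1], 2.0, "relu")) == 0.0

    def test_sigmoid_of_empty_sum(self):
        assert neuron_response([], NeuronParams([], 0.0, "sigmoid")) == 0.5

    def test_simple_arithmetic(self):
        assert neuron_response([3.0], NeuronParams([2.0], 1.0, "relu")) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            neuron_response([1, 2, 3], NeuronParams([1, 2], 0.0))

    def test_against_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(1, 20))
            x = rng.normal(size=n)
            w = rng.normal(size=n)
            b = float(rng.normal())
            acc = 0.0
            for i in range(n):  # explicit loop oracle
                acc += w[i] * x[i]
            expected = max(0.0, acc - b)
            got = neuron_response(x, NeuronParams(w, b, "relu"))
            assert got == pytest.approx(expected, abs=1e-12)


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_constant_vector_is_uniform(self):
        for c in (-100.0, 0.0, 7.3):
            assert np.allclose(softmax([c, c, c]), [1 / 3] * 3)

    def test_two_zero_case(self):
        out = softmax([2.0, 0.0])
        assert out == pytest.approx([0.880797, 0.119203], abs=1e-6)

    def test_extreme_logits_no_overflow(self):
        out = softmax([1e4, -1e4, 0.0])
        assert np.isfinite(out).all()
        assert out.sum() == pytest.approx(1.0)
        assert out[0] == pytest.approx(1.0)

    def test_empty_vector(self):
        with pytest.raises(ValidationError):
            softmax([])

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(-20, 20))
    def test_simplex_and_shift_invariance(self, z, c):
        p = softmax(z)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(softmax(np.asarray(z) + c), p, atol=1e-9)


class TestArchitecture:
    def test_dropout_bounds(self):
        get_preset("tiny")  # sanity
        ArchitectureConfig(conv_blocks=((1, 3, 4),), pool_size=4,
                           dropout_rate=0.99, input_size=48)
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(dropout_rate=1.0)

    def test_incompatible_pooling_names_layer(self):
        with pytest.raises(ConfigurationError, match="block"):
            ArchitectureConfig(conv_blocks=((1, 3, 4),), pool_size=5, input_size=48)

    def test_build_determinism(self):
        a = build_classifier("tiny", seed=3)
        b = build_classifier("tiny", seed=3)
        for (la, ka), (lb, kb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(la[ka], lb[kb])

    def test_tiny_outputs_probability_pair(self):
        model = build_classifier("tiny", seed=0)
        patch = np.random.default_rng(0).integers(0, 255, (48, 48)).astype(np.uint8)
        full = cnn.predict_proba_full(model, [patch])
        assert full.shape == (1, 2)
        assert full.sum() == pytest.approx(1.0)


class TestTraining:
    def test_zero_epochs_is_identity(self, toy_patchset):
        model = build_classifier("tiny", seed=1)
        out = train(model, toy_patchset, TrainingConfig(epochs=0, seed=0))
        for (la, ka), (lb, kb) in zip(model.parameters(), out.parameters()):
            assert np.array_equal(la[ka], lb[kb])

    def test_separable_toy_set_reaches_perfect_accuracy(self, toy_patchset):
        model = build_classifier("tiny", seed=1)
        out = train(model, toy_patchset, TrainingConfig(epochs=30, seed=0))
        assert out.history["accuracy"][-1] == 1.0
        # converged: every late-epoch loss sits below the early-epoch floor
        # (dropout keeps per-epoch loss noisy, so pointwise monotonicity is
        # not a property of stochastic training)
        head, tail = out.history["loss"][:5], out.history["loss"][-10:]
        assert max(tail) < min(head)
        assert np.mean(tail) < 0.25 * np.mean(head)

    def test_training_determinism(self, toy_patchset):
        cfg = TrainingConfig(epochs=3, seed=7)
        a = train(build_classifier("tiny", seed=1), toy_patchset, cfg)
        b = train(build_classifier("tiny", seed=1), toy_patchset, cfg)
        for (la, ka), (lb, kb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(la[ka], lb[kb])

    def test_empty_dataset_rejected(self):
        from pmfcount.dataset_builder import PatchDataset

        with pytest.raises(ValidationError):
            train(build_classifier("tiny", 0),
                  PatchDataset([], 0, 0), TrainingConfig(epochs=1))

    def test_gradients_match_finite_differences(self):
        arch = ArchitectureConfig(conv_blocks=((1, 3, 2),), pool_size=2,
                                  fc_units=4, dropout_rate=0.0, input_size=8)
        model = build_classifier(arch, seed=1)
        rng = np.random.default_rng(2)
        x = rng.random((3, 1, 8, 8))
        y = np.array([0, 1, 0])

        def loss():
            logits, _ = cnn._forward(model, x)
            p = cnn._softmax_rows(logits)
            return -np.mean(np.log(p[np.arange(3), y]))

        logits, caches = cnn._forward(model, x)
        p = cnn._softmax_rows(logits)
        onehot = np.zeros((3, 2))
        onehot[np.arange(3), y] = 1
        grads = {
            (id(layer), key): g
            for layer, gd in cnn._backward(model, caches, (p - onehot) / 3)
            for key, g in gd.items()
        }
        eps = 1e-6
        for layer, key in model.parameters():
            W, g = layer[key], grads[(id(layer), key)]
            flat_idx = rng.choice(W.size, min(4, W.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, W.shape)
                orig = W[idx]
                W[idx] = orig + eps
                lp = loss()
                W[idx] = orig - eps
                lm = loss()
                W[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], abs=1e-7, rel=1e-4)


class TestPredict:
    def test_empty_input(self):
        assert len(predict_proba(build_classifier("tiny", 0), [])) == 0

    def test_duplicate_patches_identical_probabilities(self):
        model = build_classifier("tiny", seed=0)
        patch = np.random.default_rng(1).integers(0, 255, (48, 48)).astype(np.uint8)
        p = predict_proba(model, [patch, patch])
        assert p[0] == p[1]

    def test_chunk_size_does_not_change_results(self, toy_patchset):
        model = build_classifier("tiny", seed=0)
        a = predict_proba(model, toy_patchset, chunk_size=3)
        b = predict_proba(model, toy_patchset, chunk_size=100)
        # batched linear algebra may differ in the last ulp across chunkings
        assert np.allclose(a, b, rtol=0, atol=1e-12)

    def test_class_probabilities_sum_to_one(self, toy_patchset):
        model = build_classifier("tiny", seed=0)
        full = cnn.predict_proba_full(model, toy_patchset)
        assert np.allclose(full.sum(axis=1), 1.0)

    def test_size_mismatch(self):
        model = build_classifier("tiny", seed=0)
        with pytest.raises(ValidationError):
            predict_proba(model, [np.zeros((32, 32), np.uint8)])


def test_save_load_round_trip(tmp_path, toy_patchset):
    model = train(build_classifier("tiny", seed=1), toy_patchset,
                  TrainingConfig(epochs=2, seed=0))
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    a = predict_proba(model, toy_patchset)
    b = predict_proba(loaded, toy_patchset)
    assert np.array_equal(a, b)
    assert loaded.history["loss"] == model.history["loss"]
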