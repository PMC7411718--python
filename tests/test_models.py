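import numpy as np
import pytest

from gaitid import nn
from gaitid.models import (
    FCHead,
    ModelConfig,
    SoftmaxOutput,
    build_cnn,
    build_rnn,
    ensemble_predict,
    stack_features,
    train_model,
)
from gaitid.standardize import StandardSample


def numerical_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        lp = f()
        x[i] = old - eps
        lm = f()
        x[i] = old
        g[i] = (lp - lm) / (2 * eps)
    return g


def toy_samples(n_per_class=6, d=12, n_classes=3, noise=0.02, seed=0):
    """Linearly separable cohort: class-specific constant offsets plus noise."""
    rng = np.random.default_rng(seed)
    samples = []
    for c in range(n_classes):
        for _ in range(n_per_class):
            base = (c + 1) / (n_classes + 1)
            samples.append(
                StandardSample(
                    participant_id=f"C{c}", k=1, d=d,
                    pressure=2 * np.clip(base + noise * rng.standard_normal((d, 16)), 0, 1),
                    accel=32768 * np.clip((2 * base - 1) + noise * rng.standard_normal((d, 6)), -1, 1),
                    rotation=32768 * np.clip((1 - 2 * base) + noise * rng.standard_normal((d, 6)), -1, 1),
                )
            )
    return samples


class TestShapeContracts:
    """The printed feature-map dimensions for d=87, k=1 and d=87, k=2."""

    def test_cnn_feature_maps_87(self):
        cfg = ModelConfig(modalities=("p", "a", "r"), d=87, k=1, n_classes=5, seed=0)
        model = build_cnn(cfg)
        x = np.zeros((2, 87, 16), dtype=np.float32)
        conv1, relu1, conv2, relu2, conv3, relu3, flat = model.branches["p"]
        h1 = relu1.forward(conv1.forward(x))
        assert h1.shape == (2, 87, 32)
        h2 = relu2.forward(conv2.forward(h1))
        assert h2.shape == (2, 87, 64)
        h3 = relu3.forward(conv3.forward(h2))
        assert h3.shape == (2, 87, 128)
        assert flat.forward(h3).shape == (2, 87 * 128)  # 11136 per branch

    def test_concatenated_feature_length_tri_modal(self):
        cfg = ModelConfig(modalities=("p", "a", "r"), d=87, k=1, n_classes=5, seed=0)
        model = build_cnn(cfg)
        assert model.head.fc1.W.v.shape[0] == 3 * 87 * 128  # 33408

    def test_lstm_output_shapes(self):
        cfg = ModelConfig(modalities=("p",), d=87, k=2, n_classes=5, seed=0)
        model = build_rnn(cfg)
        lstm1, lstm2 = model.branches["p"]
        x = np.zeros((3, 174, 16), dtype=np.float32)
        seq = lstm1.forward(x)
        assert seq.shape == (3, 174, 64)  # (k*d) x 64 full sequence
        last = lstm2.forward(seq)
        assert last.shape == (3, 64)  # final output vector only

    @pytest.mark.parametrize("modalities", [("p",), ("a", "r"), ("p", "a", "r")])
    @pytest.mark.parametrize("d,k", [(43, 1), (87, 2)])
    def test_forward_is_valid_softmax_everywhere(self, modalities, d, k):
        cfg = ModelConfig(modalities=modalities, d=d, k=k, n_classes=4, seed=1)
        rng = np.random.default_rng(0)
        widths = {"p": 16, "a": 6, "r": 6}
        inputs = {
            m: rng.random((3, k * d, widths[m])).astype(np.float32)
            for m in modalities
        }
        for model in (build_cnn(cfg), build_rnn(cfg)):
            probs = model.predict_proba(inputs)
            assert probs.shape == (3, 4)
            assert np.all(probs >= 0)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
            SoftmaxOutput(probs[0])  # invariants hold row-wise

    def test_uni_bi_tri_parameter_counts_grow(self):
        sizes = []
        for mods in (("p",), ("p", "a"), ("p", "a", "r")):
            cfg = ModelConfig(modalities=mods, d=43, k=1, n_classes=4, seed=0)
            sizes.append(sum(p.v.size for p in build_cnn(cfg).params))
        assert sizes[0] < sizes[1] < sizes[2]


class TestFCHead:
    def test_zero_weights_give_uniform_probs(self):
        cfg = ModelConfig(modalities=("p",), d=10, k=1, n_classes=7, seed=0)
        head = FCHead(20, cfg, np.random.default_rng(0))
        head.fc1.W.v[...] = 0
        head.fc1.b.v[...] = 0
        head.fc2.W.v[...] = 0
        head.fc2.b.v[...] = 0
        probs = head(np.random.default_rng(1).random((4, 20)).astype(np.float32))
        assert np.allclose(probs, 1 / 7, atol=1e-7)

    def test_probabilities_sum_to_one(self):
        cfg = ModelConfig(modalities=("p",), d=10, k=1, n_classes=5, seed=2)
        head = FCHead(16, cfg, np.random.default_rng(2))
        probs = head(np.random.default_rng(3).standard_normal((8, 16)).astype(np.float32))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_invariant_under_logit_shift(self):
        logits = np.random.default_rng(4).standard_normal((6, 5))
        assert np.array_equal(
            nn.softmax(logits).argmax(axis=1),
            nn.softmax(logits + 13.7).argmax(axis=1),
        )


class TestEnsemble:
    def test_idempotent_on_identical_inputs(self):
        p = np.array([0.1, 0.6, 0.3])
        assert np.allclose(ensemble_predict(p, p), p)

    def test_arithmetic(self):
        out = ensemble_predict([0.8, 0.2], [0.6, 0.4])
        assert np.allclose(out, [0.7, 0.3])

    def test_preserves_normalization(self):
        rng = np.random.default_rng(5)
        a = rng.dirichlet(np.ones(8), size=10)
        b = rng.dirichlet(np.ones(8), size=10)
        assert np.allclose(ensemble_predict(a, b).sum(axis=1), 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ensemble_predict([0.5, 0.5], [0.3, 0.3, 0.4])


class TestGradients:
    """Backprop agrees with central differences on tiny layers."""

    def test_conv1d(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv1D(2, 3, 4, rng)
        x = rng.standard_normal((2, 7, 2)).astype(np.float32)
        t = rng.standard_normal((2, 7, 3)).astype(np.float32)

        def loss():
            return float(((conv.forward(x) - t) ** 2).sum())

        dy = 2 * (conv.forward(x) - t)
        conv.W.g[...] = 0
        dx = conv.backward(dy)
        for p in (conv.W, conv.b):
            ref = numerical_grad(loss, p.v)
            assert np.abs(p.g - ref).max() <= 2e-2 * max(1.0, np.abs(ref).max())
        ref = numerical_grad(loss, x)
        assert np.abs(dx - ref).max() <= 2e-2 * max(1.0, np.abs(ref).max())

    def test_lstm(self):
        rng = np.random.default_rng(1)
        lstm = nn.LSTM(2, 3, rng, return_sequences=True)
        x = rng.standard_normal((2, 5, 2)).astype(np.float32)
        t = rng.standard_normal((2, 5, 3)).astype(np.float32)

        def loss():
            return float(((lstm.forward(x) - t) ** 2).sum())

        dy = 2 * (lstm.forward(x) - t)
        for p in lstm.params:
            p.g[...] = 0
        dx = lstm.backward(dy)
        for p in lstm.params:
            ref = numerical_grad(loss, p.v)
            assert np.abs(p.g - ref).max() <= 3e-2 * max(1.0, np.abs(ref).max())
        ref = numerical_grad(loss, x)
        assert np.abs(dx - ref).max() <= 3e-2 * max(1.0, np.abs(ref).max())


class TestTraining:
    def test_inference_is_deterministic_despite_dropout(self):
        cfg = ModelConfig(modalities=("p",), d=15, k=1, n_classes=3, seed=3)
        model = build_rnn(cfg)
        x = {"p": np.random.default_rng(0).random((4, 15, 16)).astype(np.float32)}
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_separable_classes_reach_perfect_training_accuracy(self):
        """CNN, RNN and their ensemble all fit an easy 3-class cohort."""
        samples = toy_samples()
        cfg = ModelConfig(
            modalities=("p", "a", "r"), d=12, k=1, n_classes=3, seed=4, epochs=30
        )
        inputs, labels, _ = stack_features(samples, cfg.modalities)
        probs = {}
        for build in (build_cnn, build_rnn):
            model = train_model(build(cfg), samples, cfg)
            probs[build.__name__] = model.predict_proba(inputs)
            assert model.history["accuracy"][-1] == 1.0
        ens = ensemble_predict(probs["build_cnn"], probs["build_rnn"])
        assert (ens.argmax(axis=1) == labels).all()

    def test_same_seed_reproduces_training_exactly(self):
        samples = toy_samples(n_per_class=4)
        cfg = ModelConfig(
            modalities=("p",), d=12, k=1, n_classes=3, seed=9, epochs=3
        )
        h1 = train_model(build_cnn(cfg), samples, cfg).history
        h2 = train_model(build_cnn(cfg), samples, cfg).history
        assert h1 == h2

    def test_missing_class_rejected(self):
        samples = [s for s in toy_samples() if s.participant_id != "C1"]
        cfg = ModelConfig(modalities=("p",), d=12, k=1, n_classes=3, seed=0)
        with pytest.raises(ValueError, match="class"):
            train_model(build_cnn(cfg), samples, cfg)


class TestConfigValidation:
    def test_bad_modalities(self):
        with pytest.raises(ValueError):
            ModelConfig(modalities=(), n_classes=3)
        with pytest.raises(ValueError):
            ModelConfig(modalities=("p", "x"), n_classes=3)

    def test_modalities_canonicalized(self):
        cfg = ModelConfig(modalities=("r", "p"), n_classes=3)
        assert cfg.modalities == ("p", "r")

    def test_bad_k(self):
        with pytest.raises(ValueError):
            ModelConfig(modalities=("p",), k=5, n_classes=3)
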