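"""Model construction, weight serialization, and local SGD training."""

import numpy as np
import pytest

import fedleaf as fl
from fedleaf.model_core import WeightVector, build_model, check_layouts


def _toy_data(n=12, k=3, size=(16, 16), seed=0):
    rng = np.random.default_rng(seed)
    imgs = rng.uniform(size=(n, *size, 3))
    labels = rng.integers(0, k, size=n)
    return fl.LabeledImageSet(imgs, labels, [f"c{i}" for i in range(k)])


class TestBuildModel:
    def test_seeded_init_is_reproducible(self, tiny_model_spec):
        a = build_model(tiny_model_spec).get_weights()
        b = build_model(tiny_model_spec).get_weights()
        assert (a.values == b.values).all()
        assert a.layout == b.layout

    def test_head_size_matches_n_classes(self):
        spec = fl.ModelSpec("tiny_cnn", n_classes=10, input_size=(32, 32))
        m = build_model(spec)
        x = np.zeros((2, 32, 32, 3))
        assert m.logits(x).shape == (2, 10)

    def test_backbone_without_backend_is_informative(self):
        spec = fl.ModelSpec("resnet50", n_classes=4, input_size=(224, 224))
        with pytest.raises(RuntimeError, match="resnet50"):
            build_model(spec)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            fl.ModelSpec("alexnet").validate()

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError, match="16"):
            fl.ModelSpec("tiny_cnn", input_size=(8, 8)).validate()


class TestWeightVector:
    def test_get_set_round_trip(self, tiny_model_spec):
        m = build_model(tiny_model_spec)
        w = m.get_weights()
        m.set_weights(w)
        assert (m.get_weights().values == w.values).all()

    def test_weights_fully_determine_outputs(self, tiny_model_spec):
        a = build_model(tiny_model_spec)
        b = build_model(fl.ModelSpec("tiny_cnn", 4, (32, 32), init_seed=99))
        x = np.random.default_rng(1).uniform(size=(3, 32, 32, 3))
        assert not np.allclose(a.logits(x), b.logits(x))
        b.set_weights(a.get_weights())
        assert np.allclose(a.logits(x), b.logits(x))

    def test_truncated_vector_names_parameter(self, tiny_model_spec):
        m = build_model(tiny_model_spec)
        w = m.get_weights()
        bad = WeightVector(w.values[: len(w) - 4], w.layout[:-1])
        with pytest.raises(ValueError, match="head.bias|mismatch"):
            m.set_weights(bad)

    def test_flatten_unflatten_bijection(self, tiny_model_spec):
        w = build_model(tiny_model_spec).get_weights()
        params = w.unflatten()
        assert sum(p.size for p in params.values()) == len(w)
        again = WeightVector.from_params(params)
        assert (again.values == w.values).all()
        assert again.layout == w.layout

    def test_layout_count_validation(self):
        with pytest.raises(ValueError):
            WeightVector(np.zeros(5), (("w", (2, 3)),))


class TestLocalTrain:
    def test_zero_lr_keeps_weights(self, tiny_model_spec):
        m = build_model(tiny_model_spec)
        before = m.get_weights().values.copy()
        data = _toy_data(k=4, size=(32, 32))
        after, losses = fl.local_train(m, data, epochs=2, batch_size=4,
                                       lr=0.0, seed=0)
        assert (after.values == before).all()
        assert len(losses) == 2

    def test_single_step_matches_analytic_gradient(self):
        """One sample, one full-batch epoch on the linear-softmax fixture:
        the update equals -lr times the closed-form cross-entropy gradient."""
        spec = fl.ModelSpec("linear", n_classes=3, input_size=(8, 8), init_seed=4)
        m = build_model(spec)
        data = _toy_data(n=1, k=3, size=(8, 8), seed=5)
        w0 = m.get_weights().unflatten()
        lr = 0.25

        x = data.images[0].reshape(-1)
        logits = x @ w0["fc.weight"] + w0["fc.bias"]
        p = np.exp(logits - logits.max())
        p /= p.sum()
        p[data.labels[0]] -= 1.0  # dL/dlogits for one sample
        expected_w = w0["fc.weight"] - lr * np.outer(x, p)
        expected_b = w0["fc.bias"] - lr * p

        after, _ = fl.local_train(m, data, epochs=1, batch_size=1, lr=lr, seed=0)
        got = after.unflatten()
        assert np.abs(got["fc.weight"] - expected_w).max() < 1e-6
        assert np.abs(got["fc.bias"] - expected_b).max() < 1e-6

    def test_tiny_cnn_gradients_match_finite_differences(self):
        spec = fl.ModelSpec("tiny_cnn", n_classes=3, input_size=(16, 16),
                            init_seed=5)
        m = build_model(spec)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 16, 16, 3))
        y = np.array([0, 1, 2, 1])
        _, grads = m.loss_and_grads(x, y)
        eps = 1e-6
        for name, p in m.params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = m.loss_and_grads(x, y)
                p[idx] = orig - eps
                lm, _ = m.loss_and_grads(x, y)
                p[idx] = orig
                assert abs((lp - lm) / (2 * eps) - grads[name][idx]) < 1e-5

    def test_training_is_deterministic(self, tiny_model_spec):
        data = _toy_data(n=20, k=4, size=(32, 32))
        runs = []
        for _ in range(2):
            m = build_model(tiny_model_spec)
            w, losses = fl.local_train(m, data, epochs=2, batch_size=8,
                                       lr=0.05, seed=21)
            runs.append((w.values, losses))
        assert (runs[0][0] == runs[1][0]).all()
        assert runs[0][1] == runs[1][1]

    def test_loss_decreases_on_separable_data(self, clean_dataset):
        """Mean epoch loss is non-increasing over 5 epochs for >= 4/5 seeds."""
        stats = fl.compute_channel_stats(clean_dataset)
        data = fl.normalize(clean_dataset, stats)
        ok = 0
        for seed in range(5):
            spec = fl.ModelSpec("tiny_cnn", n_classes=4, input_size=(32, 32),
                                init_seed=seed)
            m = build_model(spec)
            _, losses = fl.local_train(m, data, epochs=5, batch_size=16,
                                       lr=0.01, seed=seed)
            if all(b <= a + 1e-9 for a, b in zip(losses, losses[1:])):
                ok += 1
        assert ok >= 4

    def test_empty_data_rejected(self, tiny_model_spec):
        m = build_model(tiny_model_spec)
        empty = fl.LabeledImageSet(np.zeros((0, 32, 32, 3)), [], ["a", "b"])
        with pytest.raises(ValueError):
            fl.local_train(m, empty, epochs=1, batch_size=4, lr=0.1, seed=0)
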