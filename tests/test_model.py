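"""Architecture contracts, gradient correctness, and training behavior."""

import numpy as np
import pytest

from eatseg import nn
from eatseg.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    predict_windows,
    train_model,
    window_accuracy,
)


def param_count_formula(c: ModelConfig) -> int:
    return (
        (c.n_channels * c.L1 + 1) * c.f1
        + (c.f1 * c.L2 + 1) * c.f2
        + (c.f2 * c.L3 + 1) * c.f3
        + (c.fg + 1) * c.fc
        + c.fc + 1
    )


TINY = ModelConfig(f1=3, f2=3, f3=3, L1=5, L2=4, L3=2, fc=4, l1_penalty=0.0)


def separable_windows(n, n_samples, rng, scale=3.0):
    """Class 1 has high rotational variance; trivially separable."""
    x0 = rng.standard_normal((n // 2, n_samples, 6)) * 0.3
    x1 = rng.standard_normal((n - n // 2, n_samples, 6))
    x1[:, :, 3:] *= scale
    x = np.concatenate([x0, x1]).astype(np.float32)
    y = np.concatenate([np.zeros(n // 2), np.ones(n - n // 2)]).astype(np.float32)
    order = rng.permutation(n)
    return x[order], y[order]


class TestBuildModel:
    def test_default_parameter_count_is_7471(self):
        clf = build_model(n_samples=900)
        assert clf.n_parameters == 7471
        assert clf.n_parameters == ModelConfig().parameter_count()
        assert round(clf.n_parameters, -2) == 7500

    @pytest.mark.parametrize("cfg", [
        ModelConfig(),
        ModelConfig(f1=8, f2=12, f3=5, L1=30, L2=10, L3=3, fc=64),
        TINY,
    ])
    def test_actual_count_matches_closed_form(self, cfg):
        clf = build_model(cfg, n_samples=max(900, cfg.min_input_length()))
        assert clf.n_parameters == param_count_formula(cfg)

    def test_count_independent_of_window_length(self):
        one_min = build_model(n_samples=900)
        fifteen_min = build_model(n_samples=15 * 60 * 15)
        assert one_min.n_parameters == fifteen_min.n_parameters

    @pytest.mark.parametrize("w_min", [0.125, 0.5, 1, 2, 4, 6, 10, 15])
    def test_builds_for_all_studied_window_lengths(self, w_min):
        n = int(round(w_min * 60 * 15))
        assert build_model(n_samples=n).n_samples == n

    def test_too_short_window_reports_minimum(self):
        with pytest.raises(ValueError, match=str(ModelConfig().min_input_length())):
            build_model(n_samples=50)

    def test_untrained_output_in_unit_interval(self, rng):
        clf = build_model(n_samples=900, seed=3)
        p = clf.predict(rng.standard_normal((8, 900, 6)))
        assert np.all((p >= 0) & (p <= 1))


class TestGradients:
    def test_backprop_matches_numeric_gradients(self, rng):
        """Central-difference check on the largest-gradient entry per tensor."""
        clf = build_model(TINY, n_samples=40, seed=0)
        for layer in (*clf.convs, clf.dense, clf.out):
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
        x = rng.standard_normal((3, 40, 6))
        y = np.array([1.0, 0.0, 1.0])

        def loss():
            return nn.bce_with_logits(clf.forward_logits(x), y)[0]

        c1, c2, c3 = clf.convs
        a1, k1 = c1.forward(x, True)
        a2, k2 = c2.forward(a1, True)
        a3, k3 = c3.forward(a2, True)
        g = a3.mean(axis=1)
        h_pre = clf.dense.forward(g)
        h = nn.relu(h_pre)
        z = clf.out.forward(h)[:, 0]
        _, dz = nn.bce_with_logits(z, y)
        dh, dwo, dbo = clf.out.backward(h, dz[:, None])
        dg, dwd, dbd = clf.dense.backward(g, dh * (h_pre > 0))
        da3 = np.broadcast_to((dg / a3.shape[1])[:, None, :], a3.shape)
        dx3, dw3, db3 = c3.backward(da3, k3, True)
        dx2, dw2, db2 = c2.backward(dx3, k2, True)
        _, dw1, db1 = c1.backward(dx2, k1, False)
        grads = [dw1, db1, dw2, db2, dw3, db3, dwd, dbd, dwo, dbo]

        eps = 1e-6
        for p, g_analytic in zip(clf.parameters(), grads):
            idx = np.unravel_index(np.argmax(np.abs(g_analytic)), g_analytic.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert g_analytic[idx] == pytest.approx(numeric, rel=1e-5, abs=1e-10)


class TestTraining:
    def test_learns_separable_task(self, rng):
        """Variance-separable windows reach high training accuracy."""
        x, y = separable_windows(200, 150, rng)
        clf = build_model(n_samples=150, seed=0)
        _, hist = train_model(clf, (x, y), TrainConfig(epochs=80, seed=1))
        assert max(hist["accuracy"]) > 0.95
        assert np.all(np.isfinite(hist["loss"]))
        assert hist["loss"][-1] < hist["loss"][0]

    def test_single_class_input_rejected(self, rng):
        x = rng.standard_normal((10, 150, 6)).astype(np.float32)
        clf = build_model(n_samples=150)
        with pytest.raises(ValueError, match="both"):
            train_model(clf, (x, np.ones(10, dtype=np.float32)))

    def test_same_seed_identical_weights(self, rng):
        x, y = separable_windows(60, 150, rng)
        runs = []
        for _ in range(2):
            clf = build_model(n_samples=150, seed=5)
            train_model(clf, (x, y), TrainConfig(epochs=3, seed=5))
            runs.append([p.copy() for p in clf.parameters()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_different_seed_different_weights(self, rng):
        x, y = separable_windows(60, 150, rng)
        finals = []
        for seed in (1, 2):
            clf = build_model(n_samples=150, seed=seed)
            train_model(clf, (x, y), TrainConfig(epochs=3, seed=seed))
            finals.append(clf.parameters()[0].copy())
        assert not np.array_equal(*finals)


class TestPredict:
    def test_batch_vs_single_equivalence(self, rng):
        clf = build_model(n_samples=150, seed=2)
        x = rng.standard_normal((50, 150, 6))
        batched = clf.predict(x)
        single = np.array([clf.predict(x[i])[0] for i in range(50)])
        np.testing.assert_allclose(batched, single, atol=1e-6)

    def test_heldout_accuracy_on_separable_data(self, rng):
        x, y = separable_windows(240, 150, rng)
        clf = build_model(n_samples=150, seed=0)
        train_model(clf, (x[:160], y[:160]), TrainConfig(epochs=80, seed=1))
        acc = window_accuracy(predict_windows(clf, x[160:]), y[160:])
        assert acc > 0.9

    def test_save_load_round_trip(self, tmp_path, rng):
        clf = build_model(n_samples=150, seed=4)
        x = rng.standard_normal((5, 150, 6))
        path = tmp_path / "model.npz"
        clf.save(path)
        from eatseg.model import WindowClassifier

        back = WindowClassifier.load(path)
        np.testing.assert_array_equal(back.predict(x), clf.predict(x))


class TestWindowAccuracy:
    def test_perfect_agreement(self):
        p = np.array([0.9, 0.1, 0.7, 0.2])
        y = np.array([1, 0, 1, 0])
        assert window_accuracy(p, y) == 1.0

    def test_hand_counted_case(self):
        p = np.array([0.9, 0.2, 0.6, 0.4])
        y = np.array([1, 0, 0, 0])
        assert window_accuracy(p, y) == 0.75

    def test_chance_level_on_random_inputs(self, rng):
        p = rng.uniform(0, 1, size=4000)
        y = (rng.uniform(0, 1, size=4000) < 0.5).astype(float)
        assert window_accuracy(p, y) == pytest.approx(0.5, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_accuracy(np.array([]), np.array([]))
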