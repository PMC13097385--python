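"""Neural-net layer gradients and the fusion model's training contracts."""

import numpy as np
import pytest
from dataclasses import replace

from sarcoscreen import nn
from sarcoscreen.model import (
    Dataset,
    FusionModelConfig,
    build_model,
    predict_proba,
    train,
    train_baseline,
)

RNG = np.random.default_rng


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


class TestLayerGradients:
    """Backprop vs central differences on small random layers."""

    def _check(self, layer, x, params=True):
        y = layer.forward(x)
        w = RNG(0).normal(size=y.shape)  # random loss projection
        for p in layer.params():
            p.zero_grad()
        gx = layer.backward(w)

        def loss():
            return float(np.sum(layer.forward(x) * w))

        assert np.allclose(gx, numerical_grad(loss, x), atol=1e-5)
        if params:
            for p in layer.params():
                assert np.allclose(p.grad, numerical_grad(loss, p.value), atol=1e-5)

    def test_dense(self):
        self._check(nn.Dense(5, 3, RNG(1)), RNG(2).normal(size=(4, 5)))

    def test_conv1d(self):
        self._check(nn.Conv1D(2, 3, 5, RNG(1)), RNG(2).normal(size=(2, 2, 12)))

    def test_maxpool(self):
        self._check(nn.MaxPool1D(3), RNG(3).normal(size=(2, 2, 10)))

    def test_avgpool(self):
        self._check(nn.AvgPool1D(4), RNG(3).normal(size=(2, 2, 11)))

    def test_lstm(self):
        self._check(nn.LSTM(3, 4, RNG(4)), RNG(5).normal(size=(2, 3, 6)))

    def test_relu(self):
        self._check(nn.ReLU(), RNG(6).normal(size=(3, 7)))


def test_softmax_cross_entropy_matches_finite_differences():
    logits = RNG(7).normal(size=(5, 2))
    labels = np.array([0, 1, 1, 0, 1])
    _, grad = nn.softmax_cross_entropy(logits, labels)

    def loss_at(z):
        return nn.softmax_cross_entropy(z, labels)[0]

    num = np.zeros_like(logits)
    eps = 1e-6
    for i in np.ndindex(*logits.shape):
        z = logits.copy()
        z[i] += eps
        hi = loss_at(z)
        z[i] -= 2 * eps
        lo = loss_at(z)
        num[i] = (hi - lo) / (2 * eps)
    assert np.allclose(grad, num, atol=1e-6)


def make_toy_dataset(n=24, raw_len=128, label_from="features", seed=0):
    """Tiny synthetic dataset; the label is carried *only* by one stream
    (the other streams are constant so they cannot be memorized)."""
    rng = RNG(seed)
    labels = np.arange(n) % 2
    raw = np.zeros((n, 4, raw_len))
    feats = rng.normal(0.0, 0.3, size=(n, 9))
    demo = np.zeros((n, 3))
    if label_from == "features":
        feats[:, 0] += 3.0 * labels
    elif label_from == "raw":
        raw = rng.normal(0.0, 1.0, size=(n, 4, raw_len))
        raw *= (1.0 + 2.0 * labels)[:, None, None]
    return Dataset(
        raw=raw,
        features=feats,
        demographics=demo,
        labels=labels,
        subject_ids=np.array([f"T{i}" for i in range(n)]),
    )


FAST = FusionModelConfig(epochs=5, batch_size=8, downsample=1, dropout=0.0)


class TestFusionModel:
    def test_shape_contract_and_simplex_output(self):
        net = build_model(FAST, n_raw_channels=4, raw_len=128)
        raw = RNG(1).normal(size=(6, 4, 128))
        logits = net.forward(raw, RNG(2).normal(size=(6, 9)), RNG(3).normal(size=(6, 3)))
        probs = nn.softmax(logits)
        assert probs.shape == (6, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_default_lstm_width_is_64(self):
        net = build_model(FusionModelConfig(), n_raw_channels=4, raw_len=1250)
        assert net.temporal.hidden == 64

    def test_probabilities_sum_to_one_on_random_inputs(self):
        net = build_model(FAST, n_raw_channels=4, raw_len=128)
        for s in range(5):
            probs = nn.softmax(
                net.forward(
                    RNG(s).normal(size=(8, 4, 128)),
                    RNG(s + 1).normal(size=(8, 9)),
                    RNG(s + 2).normal(size=(8, 3)),
                )
            )
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_feature_stream_reaches_full_accuracy(self):
        ds = make_toy_dataset(label_from="features")
        config = replace(FAST, epochs=50)
        trained = train(config, ds)
        assert (predict_proba(trained, ds).argmax(axis=1) == ds.labels).all()
        # smoothed loss decreases on this separable problem
        losses = [h["loss"] for h in trained.training_history]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_training_is_bit_reproducible(self):
        ds = make_toy_dataset()
        a = train(FAST, ds)
        b = train(FAST, ds)
        assert a.weight_hash() == b.weight_hash()
        assert len(a.training_history) == FAST.epochs

    def test_label_flip_inverts_held_out_prediction(self):
        ds = make_toy_dataset(n=32, label_from="features")
        flipped = Dataset(
            raw=ds.raw, features=ds.features, demographics=ds.demographics,
            labels=1 - ds.labels, subject_ids=ds.subject_ids,
        )
        config = replace(FAST, epochs=40)
        # canonical held-out probes: only the informative feature is set
        feats = np.zeros((4, 9))
        feats[:, 0] = [0.0, 3.0, 0.0, 3.0]
        holdout = Dataset(
            raw=np.zeros((4, 4, ds.raw.shape[2])),
            features=feats,
            demographics=np.zeros((4, 3)),
            labels=np.array([0, 1, 0, 1]),
            subject_ids=np.array(["H0", "H1", "H2", "H3"]),
        )
        pred_a = predict_proba(train(config, ds), holdout).argmax(axis=1)
        pred_b = predict_proba(train(config, flipped), holdout).argmax(axis=1)
        assert np.array_equal(pred_a, 1 - pred_b)

    def test_prediction_purity_on_duplicated_samples(self):
        ds = make_toy_dataset()
        trained = train(FAST, ds)
        dup = ds.subset(np.array([0, 0, 0]))
        probs = predict_proba(trained, dup)
        assert np.allclose(probs[0], probs[1]) and np.allclose(probs[0], probs[2])

    def test_single_class_training_set_raises(self):
        ds = make_toy_dataset()
        bad = ds.subset(np.flatnonzero(ds.labels == 0))
        with pytest.raises(ValueError):
            train(FAST, bad)

    @pytest.mark.parametrize("modality", ["both", "semg", "strain"])
    @pytest.mark.parametrize("aux", [True, False])
    def test_ablation_contract_builds_and_trains(self, modality, aux):
        ds = make_toy_dataset(n=8)
        config = replace(
            FAST, epochs=1, modality=modality, use_features=aux, use_demo=aux
        )
        trained = train(config, ds)
        assert predict_proba(trained, ds).shape == (8, 2)


class TestBaselines:
    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            train_baseline("mlp", make_toy_dataset())

    def test_rf_solves_separable_feature_table(self):
        ds = make_toy_dataset(label_from="features")
        model = train_baseline("rf", ds, seed=0)
        assert (model.predict_proba(ds).argmax(axis=1) == ds.labels).all()

    def test_svm_decision_threshold_on_one_informative_feature(self):
        """Symmetric 1-D classes: the decision flips at the midpoint."""
        n = 40
        feats = np.zeros((n, 9))
        feats[: n // 2, 0] = np.linspace(-2.0, -1.0, n // 2)
        feats[n // 2:, 0] = np.linspace(1.0, 2.0, n // 2)
        ds = Dataset(
            raw=np.zeros((n, 4, 16)),
            features=feats,
            demographics=np.zeros((n, 3)),
            labels=np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)],
            subject_ids=np.array([f"S{i}" for i in range(n)]),
        )
        model = train_baseline("svm", ds, seed=0)
        probe = ds.subset(np.arange(4))
        probe.features = np.zeros((4, 9))
        probe.features[:, 0] = [-1.5, -0.5, 0.5, 1.5]
        pred = model.predict_proba(probe).argmax(axis=1)
        assert np.array_equal(pred, [0, 0, 1, 1])

    @pytest.mark.parametrize("kind", ["cnn", "lstm"])
    def test_raw_only_networks_learn_amplitude_labels(self, kind):
        ds = make_toy_dataset(n=24, raw_len=128, label_from="raw")
        config = replace(FAST, epochs=60)
        model = train_baseline(kind, ds, seed=0, config=config)
        acc = (model.predict_proba(ds).argmax(axis=1) == ds.labels).mean()
        assert acc >= 0.9
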