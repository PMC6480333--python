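"""Network construction, training mechanics, decision rule, persistence."""

import numpy as np
import pytest

from chimeranet.encoding import EncodingSpec
from chimeranet.evaluation import table_grid
from chimeranet.exceptions import EmptyClassError, ShapeInfeasibleError
from chimeranet.model import (
    FusionCNNClassifier,
    ModelConfig,
    Prediction,
    TrainConfig,
    build_network,
    confidence_zone,
    label_from_prob,
    predictions_table,
)


def _toy_data(n=48, length=60, seed=0):
    """Binary-separable toy tensors: class 1 has channel 0 hot in a window."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, length, 22), dtype=np.uint8)
    codes = rng.integers(1, 21, size=(n, length))
    X[np.arange(n)[:, None], np.arange(length)[None, :], codes] = 1
    y = np.array(["Onco", "NotOnco"] * (n // 2))
    for i in range(0, n, 2):
        pos = int(rng.integers(0, length - 6))
        X[i, pos : pos + 6, :] = 0
        X[i, pos : pos + 6, 0] = 1
    return X, y


def _small_clf(**kw):
    defaults = dict(
        conv_kernel=4, pool_kernel=3, n_filters=(4, 6), dense_units=8,
        batch_size=16, max_epochs=20, patience=20, learning_rate=0.05,
        momentum=0.9, validation_fraction=0.0, random_state=0,
    )
    defaults.update(kw)
    return FusionCNNClassifier(**defaults)


class TestArchitecture:
    def test_conf10_feature_lengths(self):
        cfg = ModelConfig(conv_kernel=10, pool_kernel=5, input_spec=EncodingSpec(n=5000))
        assert cfg.feature_lengths() == [4991, 998, 989, 197]

    @pytest.mark.parametrize("cfg", table_grid(), ids=lambda c: c.name)
    def test_shape_formula_matches_built_network(self, cfg):
        """floor((L - conv + 1)/pool) applied twice agrees with live introspection."""
        rng = np.random.default_rng(0)
        net = build_network(cfg, rng)
        x = np.zeros((2, cfg.input_spec.n, cfg.input_spec.c), dtype=np.float32)
        lengths = []
        for layer in net.layers[:10]:
            x = layer.forward(x, train=False)
            if type(layer).__name__ in ("Conv1D", "MaxPool1D"):
                lengths.append(x.shape[1])
        assert lengths == cfg.feature_lengths()

    def test_oversized_kernel_infeasible(self):
        cfg = ModelConfig(conv_kernel=6000, input_spec=EncodingSpec(n=5000))
        with pytest.raises(ShapeInfeasibleError):
            cfg.feature_lengths()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_kernel=0)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            TrainConfig(patience=60, max_epochs=50)


class TestGradients:
    def test_backprop_matches_numeric_gradients(self):
        """Analytic gradients agree with central differences on a float64 network."""
        rng = np.random.default_rng(0)
        cfg = ModelConfig(
            conv_kernel=4, pool_kernel=3, dropout=0.0, n_filters=(3, 4),
            dense_units=8, input_spec=EncodingSpec(n=60, c=5),
        )
        net = build_network(cfg, rng, dtype=np.float64)
        net.layers[0].input_layer = False  # exercise the full input gradient path too
        x = rng.normal(size=(6, 60, 5))
        y = rng.integers(0, 2, 6).astype(float)

        def loss_at():
            z = net.forward_logits(x, train=True)
            return net.bce_loss(net.sigmoid(z), y)

        net.train_batch_gradients(x, y)
        grads = {k: layer.grads[n].copy() for k, layer, n, _ in net.parameters()}
        eps = 1e-6
        for key, layer, name, w in net.parameters():
            flat = w.ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_at()
                flat[i] = orig - eps
                lm = loss_at()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                # conv biases feed straight into batch-norm, so their true
                # gradient is exactly zero; compare with a mixed tolerance
                assert abs(num - ana) <= 1e-6 + 1e-4 * (abs(num) + abs(ana)), (key, i)


class TestTraining:
    def test_learns_separable_toy_problem(self):
        X, y = _toy_data()
        est = _small_clf().fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.9

    def test_constant_labels_raise(self):
        X, _ = _toy_data()
        with pytest.raises(EmptyClassError):
            _small_clf().fit(X, np.array(["Onco"] * len(X)))

    def test_seeded_determinism(self):
        X, y = _toy_data()
        p1 = _small_clf(max_epochs=3).fit(X, y).oncogenic_probability(X)
        p2 = _small_clf(max_epochs=3).fit(X, y).oncogenic_probability(X)
        np.testing.assert_array_equal(p1, p2)

    def test_history_recorded_and_early_stop_restores_best(self):
        X, y = _toy_data()
        est = _small_clf(max_epochs=6, patience=2, validation_fraction=0.25).fit(X, y)
        assert len(est.history_["train_loss"]) >= 3
        assert est.best_epoch_ >= 0
        assert np.isfinite(est.history_["val_loss"]).all()

    def test_class_symmetry_after_label_swap(self):
        """Swapping training labels approximately flips the score distribution."""
        X, y = _toy_data()
        y_swapped = np.where(y == "Onco", "NotOnco", "Onco")
        p = _small_clf().fit(X, y).oncogenic_probability(X)
        q = _small_clf().fit(X, y_swapped).oncogenic_probability(X)
        # scores should anticorrelate strongly on a symmetric problem
        assert np.corrcoef(p, q)[0, 1] < -0.5


class TestInference:
    def test_outputs_in_open_interval_and_order_preserving(self):
        X, y = _toy_data()
        est = _small_clf(max_epochs=2).fit(X, y)
        p = est.oncogenic_probability(X)
        assert np.all((p > 0) & (p < 1))
        np.testing.assert_array_equal(p[::-1], est.oncogenic_probability(X[::-1]))

    def test_duplicated_rows_and_batching_invariance(self):
        X, y = _toy_data(n=20)
        est = _small_clf(max_epochs=2, batch_size=7).fit(X, y)
        dup = np.repeat(X[:3], 2, axis=0)
        p = est.oncogenic_probability(dup)
        np.testing.assert_array_equal(p[::2], p[1::2])
        one_by_one = np.concatenate([est.oncogenic_probability(X[i : i + 1]) for i in range(6)])
        np.testing.assert_allclose(est.oncogenic_probability(X[:6]), one_by_one, atol=1e-7)

    def test_shape_mismatch_raises(self):
        X, y = _toy_data()
        est = _small_clf(max_epochs=1).fit(X, y)
        with pytest.raises(ValueError):
            est.oncogenic_probability(np.zeros((2, 30, 22)))

    def test_predict_proba_columns_sum_to_one(self):
        X, y = _toy_data()
        est = _small_clf(max_epochs=1).fit(X, y)
        P = est.predict_proba(X[:5])
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert list(est.classes_) == ["NotOnco", "Onco"]


class TestPersistence:
    def test_save_load_round_trip_predictions(self, tmp_path):
        X, y = _toy_data()
        est = _small_clf(max_epochs=2).fit(X, y)
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = FusionCNNClassifier.load(path)
        np.testing.assert_array_equal(
            est.oncogenic_probability(X), loaded.oncogenic_probability(X)
        )
        assert list(loaded.classes_) == list(est.classes_)


class TestDecisionRule:
    def test_threshold_and_zone_boundaries_exhaustively(self):
        """Eq-style decision rule on a fine probability grid: >= 0.5 is Onco;
        zones open at 0.2 and 0.8 (boundary values are uncertain)."""
        grid = np.round(np.linspace(0, 1, 1001), 6)
        labels = label_from_prob(grid)
        zones = confidence_zone(grid)
        for p, lab, zone in zip(grid, labels, zones):
            assert lab == ("Onco" if p >= 0.5 else "NotOnco")
            if p < 0.2:
                assert zone == "high_conf_notonco"
            elif p > 0.8:
                assert zone == "high_conf_onco"
            else:
                assert zone == "uncertain"
        # zone implies label consistency
        assert all(l == "Onco" for l, z in zip(labels, zones) if z == "high_conf_onco")
        assert all(l == "NotOnco" for l, z in zip(labels, zones) if z == "high_conf_notonco")

    @pytest.mark.parametrize("p,label", [(0.5, "Onco"), (0.49, "NotOnco"), (0.0, "NotOnco"), (1.0, "Onco")])
    def test_label_examples(self, p, label):
        assert label_from_prob(p) == label

    @pytest.mark.parametrize(
        "p,zone", [(0.1, "high_conf_notonco"), (0.2, "uncertain"), (0.8, "uncertain"), (0.85, "high_conf_onco")]
    )
    def test_zone_examples(self, p, zone):
        assert confidence_zone(p) == zone

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            label_from_prob(1.5)
        with pytest.raises(ValueError):
            confidence_zone(-0.1)

    def test_prediction_and_table(self):
        pred = Prediction.from_prob("f1", 0.93)
        assert pred.label == "Onco" and pred.zone == "high_conf_onco"
        table = predictions_table(["a", "b"], [0.123456789, 0.4])
        assert list(table.columns) == ["fusion_id", "prob", "label", "zone"]
        assert table["prob"].iloc[0] == pytest.approx(0.123457)
        assert list(table["label"]) == ["NotOnco", "NotOnco"]
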