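"""Confusion matrices, metrics, probability bins, CV and the architecture grid."""

import numpy as np
import pytest

from chimeranet.evaluation import (
    ConfusionMatrix,
    CVResult,
    bin_probabilities,
    confusion_matrix,
    cv_report_frame,
    grid_search,
    high_confidence_metrics,
    metrics,
    table_grid,
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["Onco"] * 3 + ["NotOnco"] * 3
        cm = confusion_matrix(labels, labels)
        assert cm.counts["Onco"]["Onco"] == 3 and cm.counts["NotOnco"]["NotOnco"] == 3
        assert cm.counts["Onco"]["NotOnco"] == 0 and cm.counts["NotOnco"]["Onco"] == 0

    def test_all_onco_predictions(self):
        cm = confusion_matrix(["Onco"] * 4, ["Onco", "NotOnco", "Onco", "NotOnco"])
        assert cm.counts["Onco"] == {"Onco": 2, "NotOnco": 2}
        assert cm.counts["NotOnco"] == {"Onco": 0, "NotOnco": 0}

    def test_empty_or_mismatched_inputs_raise(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [])
        with pytest.raises(ValueError):
            confusion_matrix(["Onco"], ["Onco", "NotOnco"])

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        preds = rng.choice(["Onco", "NotOnco"], 57)
        truths = rng.choice(["Onco", "NotOnco"], 57)
        assert confusion_matrix(preds, truths).total == 57


class TestMetrics:
    def test_published_test_set_worked_example(self):
        """The worked example: 152/52/80/180 gives 71.55% accuracy and
        Onco precision/recall 74.50/65.51 (source truncates decimals)."""
        cm = ConfusionMatrix.from_counts(152, 52, 80, 180)
        rep = metrics(cm)
        assert rep.accuracy == pytest.approx(71.55, abs=0.005)
        assert rep.precision_onco == pytest.approx(74.50, abs=0.02)
        assert rep.recall_onco == pytest.approx(65.51, abs=0.02)
        assert rep.n == 464

    def test_identity_matrix_all_100(self):
        rep = metrics(ConfusionMatrix.from_counts(5, 0, 0, 5))
        assert rep.accuracy == 100.0
        assert rep.precision_onco == rep.recall_onco == 100.0
        assert rep.precision_notonco == rep.recall_notonco == 100.0

    def test_zero_denominator_reported_as_undefined(self):
        rep = metrics(ConfusionMatrix.from_counts(0, 0, 2, 2))
        assert rep.precision_onco is None
        assert rep.recall_onco == 0.0

    def test_idempotent_with_raw_recomputation(self):
        rng = np.random.default_rng(1)
        preds = rng.choice(["Onco", "NotOnco"], 200)
        truths = rng.choice(["Onco", "NotOnco"], 200)
        cm = confusion_matrix(preds, truths)
        rep1 = metrics(cm).to_dict()
        rep2 = metrics(ConfusionMatrix(counts={p: dict(a) for p, a in cm.counts.items()})).to_dict()
        assert rep1 == rep2


class TestProbabilityBins:
    def test_small_example(self):
        s = bin_probabilities([0.05, 0.15, 0.95], ["NotOnco", "Onco", "Onco"])
        t = s.table
        assert t.loc[0, "n_notonco"] == 1 and t.loc[0, "n_onco"] == 0
        assert t.loc[1, "n_onco"] == 1
        assert t.loc[9, "n_onco"] == 1
        assert s.n == 3

    def test_probability_one_lands_in_last_bin(self):
        s = bin_probabilities([1.0], ["Onco"])
        assert s.table.loc[9, "n_onco"] == 1

    def test_totals_conserved(self):
        rng = np.random.default_rng(2)
        probs = rng.random(500)
        truths = rng.choice(["Onco", "NotOnco"], 500)
        assert bin_probabilities(probs, truths).n == 500

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bin_probabilities([1.2], ["Onco"])


class TestHighConfidence:
    def test_all_uncertain_returns_undefined(self):
        rep, frac = high_confidence_metrics([0.4, 0.6], ["Onco", "NotOnco"])
        assert rep is None and frac == 0.0

    def test_two_confident_correct_instances(self):
        rep, frac = high_confidence_metrics([0.05, 0.9], ["NotOnco", "Onco"])
        assert rep.accuracy == 100.0 and frac == 1.0

    def test_fraction_matches_hand_count(self):
        probs = [0.1, 0.15, 0.5, 0.79, 0.81, 0.95]
        truths = ["NotOnco", "Onco", "Onco", "NotOnco", "Onco", "Onco"]
        rep, frac = high_confidence_metrics(probs, truths)
        assert frac == pytest.approx(4 / 6)
        # in-zone: 0.1 (correct), 0.15 (wrong), 0.81 (correct), 0.95 (correct)
        assert rep.accuracy == pytest.approx(75.0)


class TestGrid:
    def test_grid_enumerates_12_named_configurations(self):
        grid = table_grid()
        assert len(grid) == 12
        assert [c.name for c in grid] == [f"Conf_{i}" for i in range(1, 13)]
        by_name = {c.name: c for c in grid}
        assert (by_name["Conf_10"].conv_kernel, by_name["Conf_10"].pool_kernel,
                by_name["Conf_10"].dropout) == (10, 5, 0.1)
        assert (by_name["Conf_1"].conv_kernel, by_name["Conf_1"].pool_kernel,
                by_name["Conf_1"].dropout) == (3, 2, 0.1)
        assert (by_name["Conf_8"].conv_kernel, by_name["Conf_8"].pool_kernel,
                by_name["Conf_8"].dropout) == (5, 3, 0.3)
        # Conv/Pool pairs x dropout levels
        assert {(c.conv_kernel, c.pool_kernel) for c in grid} == {(3, 2), (5, 2), (5, 3), (10, 5)}
        assert sorted({c.dropout for c in grid}) == [0.1, 0.3, 0.5]

    def test_cv_result_stats_recomputable(self):
        from chimeranet.model import ModelConfig

        accs = [0.70, 0.72, 0.68, 0.75]
        res = CVResult("x", ModelConfig(), accs)
        assert res.median == pytest.approx(np.median(accs))
        assert res.std == pytest.approx(np.std(accs, ddof=1))

    def test_report_frame_columns(self):
        from chimeranet.model import ModelConfig

        frame = cv_report_frame([CVResult("Conf_1", ModelConfig(name="Conf_1"), [0.7, 0.71])])
        assert list(frame.columns) == [
            "Name", "Conv", "Pool", "Drop", "CrossValidationAccuracy", "StandardDeviation",
        ]


class TestSelectionRule:
    def _result(self, name, accs):
        from chimeranet.model import ModelConfig

        return CVResult(name, ModelConfig(name=name), accs)

    def test_grid_of_one_selects_it(self, monkeypatch):
        import chimeranet.evaluation as ev

        res = self._result("only", [0.7, 0.7])
        monkeypatch.setattr(ev, "cross_validate", lambda *a, **k: res)
        from chimeranet.model import ModelConfig, TrainConfig

        ranked, selected = ev.grid_search([], [ModelConfig(name="only")], TrainConfig())
        assert selected.name == "only"

    def test_equal_median_prefers_lower_std(self, monkeypatch):
        import chimeranet.evaluation as ev

        results = iter(
            [self._result("noisy", [0.60, 0.80]), self._result("stable", [0.69, 0.71])]
        )
        monkeypatch.setattr(ev, "cross_validate", lambda *a, **k: next(results))
        from chimeranet.model import ModelConfig, TrainConfig

        _, selected = ev.grid_search(
            [], [ModelConfig(name="noisy"), ModelConfig(name="stable")], TrainConfig()
        )
        assert selected.name == "stable"

    def test_high_std_config_excluded_despite_higher_median(self, monkeypatch):
        import chimeranet.evaluation as ev

        results = iter(
            [
                self._result("wild", [0.50, 0.95, 0.96]),
                self._result("good", [0.70, 0.71, 0.72]),
                self._result("ok", [0.65, 0.66, 0.67]),
            ]
        )
        monkeypatch.setattr(ev, "cross_validate", lambda *a, **k: next(results))
        from chimeranet.model import ModelConfig, TrainConfig

        _, selected = ev.grid_search(
            [], [ModelConfig(name=n) for n in ("wild", "good", "ok")], TrainConfig()
        )
        assert selected.name == "good"


class TestCrossValidateScaledDown:
    def test_two_reps_two_folds_on_motif_data(self, motif_dataset):
        """Scaled-down repeated CV returns T accuracy values with recomputable stats
        and is reproducible under the same master seed."""
        from chimeranet.encoding import EncodingSpec
        from chimeranet.evaluation import cross_validate
        from chimeranet.model import ModelConfig, TrainConfig

        cfg = ModelConfig(
            conv_kernel=4, pool_kernel=3, n_filters=(4, 6), dense_units=8,
            input_spec=EncodingSpec(n=120), name="tiny",
        )
        tcfg = TrainConfig(max_epochs=2, patience=2, validation_fraction=0.0, batch_size=32)
        res = cross_validate(motif_dataset, cfg, tcfg, k=2, T=2, seed=3)
        assert len(res.accuracies) == 2
        assert all(0.0 <= a <= 1.0 for a in res.accuracies)
        assert res.median == pytest.approx(np.median(res.accuracies))
        res2 = cross_validate(motif_dataset, cfg, tcfg, k=2, T=2, seed=3)
        assert res2.accuracies == res.accuracies
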