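"""Forest training contracts: metrics, determinism, importance behaviour."""

import warnings

import numpy as np
import pytest

from readthru.features import default_schema
from readthru.forest import (
    ModelSpec,
    auroc,
    default_mtry_grid,
    nrmse,
    permutation_importance,
    predict_readthrough,
    train_classifier,
    train_regressor,
)


class TestNrmse:
    def test_perfect_fit_is_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert nrmse(y, y) == 0.0

    def test_closed_form(self):
        assert nrmse(np.array([0.0, 1.0]), np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_matches_two_line_oracle(self, rng):
        for _ in range(20):
            y = rng.normal(size=50)
            yhat = rng.normal(size=50)
            expected = np.sqrt(np.mean((y - yhat) ** 2)) / (y.max() - y.min())
            assert nrmse(y, yhat) == pytest.approx(expected, abs=1e-12)

    def test_zero_range_fatal(self):
        with pytest.raises(ValueError, match="range"):
            nrmse(np.ones(5), np.zeros(5))


class TestAuroc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["high", "high", "low", "low"])
        assert auroc(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        scores = np.zeros(10)
        labels = np.array(["high"] * 5 + ["low"] * 5)
        assert auroc(scores, labels) == 0.5

    def test_single_class_fatal(self):
        with pytest.raises(ValueError):
            auroc(np.arange(4.0), np.array(["high"] * 4))


class TestTrainingContracts:
    def test_mtry_grid_default_members(self):
        grid = default_mtry_grid(77, "regression")
        assert grid == (1, 8, 9, 26, 39)
        assert default_mtry_grid(2, "regression") == (1, 2)

    def test_identical_seed_reproduces_model(self, strong_sim, full_schema):
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        spec = ModelSpec(task="regression", n_trees=20, seed=5, mtry_grid=(5, 20))
        m1 = train_regressor(strong_sim["features"], y, spec, full_schema)
        m2 = train_regressor(strong_sim["features"], y, spec, full_schema)
        assert m1.mtry == m2.mtry
        p1 = predict_readthrough(m1, strong_sim["features"])
        p2 = predict_readthrough(m2, strong_sim["features"])
        assert np.array_equal(p1, p2)

    def test_training_set_fit_beats_cv_fit(self, tiny_regressor, strong_sim):
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        preds = predict_readthrough(tiny_regressor, strong_sim["features"])
        assert nrmse(y, preds) < tiny_regressor.cv_metric

    def test_duplicate_rows_get_identical_predictions(self, tiny_regressor, strong_sim):
        table = strong_sim["features"].iloc[[0, 0, 1, 1]].reset_index(drop=True)
        preds = predict_readthrough(tiny_regressor, table)
        assert preds[0] == preds[1] and preds[2] == preds[3]

    def test_constant_target_fatal(self, small_sim, full_schema):
        with pytest.raises(ValueError, match="constant|range"):
            train_regressor(small_sim["features"],
                            np.zeros(len(small_sim["features"])),
                            ModelSpec(task="regression"), full_schema)

    def test_too_few_records_fatal(self, small_sim, full_schema):
        table = small_sim["features"].head(20)
        with pytest.raises(ValueError, match="50"):
            train_regressor(table, np.arange(20.0),
                            ModelSpec(task="regression"), full_schema)

    def test_signal_model_beats_negative_control_model(self, strong_sim, full_schema):
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        spec = ModelSpec(task="regression", n_trees=50, seed=2, tune=False)
        full = train_regressor(strong_sim["features"], y, spec, full_schema)
        nc_only = full_schema.subset("nc_only", {"nc_number", "nc_letter"})
        null = train_regressor(strong_sim["features"], y, spec, nc_only)
        assert full.cv_metric < null.cv_metric - 0.05

    def test_noise_only_target_matches_mean_predictor(self, small_sim, full_schema):
        rng = np.random.default_rng(8)
        y = rng.normal(size=len(small_sim["features"]))
        spec = ModelSpec(task="regression", n_trees=50, seed=2, tune=False)
        model = train_regressor(small_sim["features"], y, spec, full_schema)
        null_nrmse = y.std() / (y.max() - y.min())
        assert model.cv_metric == pytest.approx(null_nrmse, abs=0.03)

    def test_unseen_level_bucketed_with_warning(self, tiny_regressor, strong_sim):
        table = strong_sim["features"].head(5).copy()
        table.loc[table.index[0], "psite_codon"] = "ZZZ"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            preds = predict_readthrough(tiny_regressor, table)
        assert len(preds) == 5
        assert any("psite_codon" in str(w.message) for w in caught)


class TestClassifier:
    @staticmethod
    def extremes(sim, fraction=0.3):
        truth = sim["truth"].copy()
        y = truth["true_log2_re"]
        lo, hi = y.quantile(fraction), y.quantile(1 - fraction)
        truth["label"] = np.where(y <= lo, "low", np.where(y >= hi, "high", "none"))
        keep = truth["label"] != "none"
        table = sim["features"].loc[keep.to_numpy()].reset_index(drop=True)
        return table, truth.loc[keep, "label"].to_numpy()

    def test_planted_signal_gives_high_auroc(self, strong_sim, full_schema):
        table, labels = self.extremes(strong_sim)
        spec = ModelSpec(task="classification", n_trees=50, seed=3, tune=False)
        model = train_classifier(table, labels, spec, full_schema)
        assert model.cv_metric > 0.8

    def test_shuffled_labels_give_chance_auroc(self, strong_sim, full_schema):
        table, labels = self.extremes(strong_sim)
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = ModelSpec(task="classification", n_trees=30, seed=seed, tune=False)
            model = train_classifier(table, rng.permutation(labels), spec, full_schema)
            aucs.append(model.cv_metric)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_folds_exceeding_class_count_fatal(self, small_sim, full_schema):
        table = small_sim["features"].head(4)
        labels = np.array(["high", "high", "low", "low"])
        with pytest.raises(ValueError, match="class"):
            train_classifier(table, labels,
                             ModelSpec(task="classification", cv_folds=5),
                             full_schema)

    def test_single_class_fatal(self, small_sim, full_schema):
        table = small_sim["features"].head(60)
        with pytest.raises(ValueError, match="high"):
            train_classifier(table, np.array(["high"] * 60),
                             ModelSpec(task="classification"), full_schema)


class TestImportance:
    def test_perfect_predictor_dominates(self, strong_sim, full_schema):
        # make one numeric feature a monotone function of the target
        table = strong_sim["features"].copy()
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        table["utr3_len"] = np.argsort(np.argsort(y))
        spec = ModelSpec(task="regression", n_trees=40, seed=1, tune=False)
        model = train_regressor(table, y, spec, full_schema)
        imp = permutation_importance(model, table, y).set_index("feature")
        assert imp.loc["utr3_len", "rank"] == 1

    def test_constant_feature_scores_zero_with_note(self, strong_sim, full_schema):
        table = strong_sim["features"].copy()
        table["cds_len"] = 300
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        spec = ModelSpec(task="regression", n_trees=30, seed=1, tune=False)
        model = train_regressor(table, y, spec, full_schema)
        imp = permutation_importance(model, table, y).set_index("feature")
        assert imp.loc["cds_len", "importance"] == 0.0
        assert imp.loc["cds_len", "note"] == "constant feature"

    def test_negative_controls_present_in_table(self, tiny_regressor, strong_sim):
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        imp = permutation_importance(tiny_regressor, strong_sim["features"], y)
        assert {"nc_number", "nc_letter"} <= set(imp["feature"])

    def test_collinear_pair_shares_importance(self, strong_sim, full_schema):
        # duplicate the 3'-UTR length into another numeric slot: neither copy
        # should go negative, and together they should carry a similar raw
        # importance to the single-copy run
        y = strong_sim["truth"]["true_log2_re"].to_numpy()
        spec = ModelSpec(task="regression", n_trees=60, seed=4, tune=False)
        single = permutation_importance(
            train_regressor(strong_sim["features"], y, spec, full_schema),
            strong_sim["features"], y).set_index("feature")
        table = strong_sim["features"].copy()
        table["utr5_len"] = table["utr3_len"]
        dup = permutation_importance(
            train_regressor(table, y, spec, full_schema), table, y
        ).set_index("feature")
        tol = 0.02
        assert dup.loc["utr3_len", "raw_mean"] >= -tol
        assert dup.loc["utr5_len", "raw_mean"] >= -tol
        pair_sum = dup.loc["utr3_len", "raw_mean"] + dup.loc["utr5_len", "raw_mean"]
        solo = single.loc["utr3_len", "raw_mean"]
        assert pair_sum == pytest.approx(solo, rel=1.0, abs=0.05)
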