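import numpy as np
import pandas as pd
import pytest

from dietsim.classify import (confusion_metrics, f1_from_precision_recall,
                              fit_adequacy_regression, mape_pct, r_squared,
                              rmse, summary_from_class_rates,
                              train_pattern_classifier)

PATTERNS = ("Mediterranean", "Western", "Plant-based", "Mixed")


def _tally_oracle(y_true, y_pred, labels):
    """Brute-force per-class tallies, independent of the implementation."""
    out = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out[lab] = (precision, recall, f1, tp + fn)
    accuracy = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return out, accuracy


class TestConfusionMetrics:
    def test_matches_brute_force_oracle_on_random_labels(self, rng):
        labels = list("abcd")
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y_true = rng.choice(labels, n)
            y_pred = rng.choice(labels, n)
            rep = confusion_metrics(y_true, y_pred, labels=labels)
            oracle, acc = _tally_oracle(y_true, y_pred, labels)
            assert rep.accuracy == pytest.approx(acc)
            for lab in labels:
                m = rep.per_class[lab]
                assert (m.precision, m.recall, m.f1, m.support) == \
                    pytest.approx(oracle[lab])

    def test_perfect_prediction(self):
        y = ["a", "b", "a", "c"]
        rep = confusion_metrics(y, y)
        assert rep.accuracy == 1.0
        assert all(m.f1 == 1.0 for m in rep.per_class.values())

    def test_row_sums_equal_supports(self, rng):
        y_true = rng.choice(list("ab"), 50)
        y_pred = rng.choice(list("ab"), 50)
        rep = confusion_metrics(y_true, y_pred)
        for i, lab in enumerate(rep.labels):
            assert rep.confusion_counts[i].sum() == rep.per_class[lab].support

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_undefined_class_scores_zero(self):
        rep = confusion_metrics(["a", "a", "b"], ["a", "a", "a"])
        assert rep.per_class["b"].precision == 0.0
        assert rep.per_class["b"].f1 == 0.0


class TestReferenceClassMetricArithmetic:
    """Checks against the reference per-class classification table."""

    PRECISIONS = (0.522, 0.396, 0.500, 0.378)
    RECALLS = (0.112, 0.304, 0.063, 0.792)
    SUPPORTS = (107, 125, 64, 154)

    def test_f1_from_rounded_rates(self):
        # printed per-class rates reproduce the macro F1 at 3 decimals
        agg = summary_from_class_rates(self.PRECISIONS, self.RECALLS, self.SUPPORTS)
        assert round(agg["macro_f1"], 3) == 0.288

    def test_accuracy_is_support_weighted_recall(self):
        agg = summary_from_class_rates(self.PRECISIONS, self.RECALLS, self.SUPPORTS)
        assert round(agg["accuracy"], 3) == 0.391

    def test_f1_harmonic_mean_identity(self):
        assert f1_from_precision_recall(0.5, 0.5) == pytest.approx(0.5)
        assert f1_from_precision_recall(0.0, 0.0) == 0.0
        assert f1_from_precision_recall(1.0, 1.0) == 1.0


class TestClassifier:
    def test_separable_clusters_classified_accurately(self, rng):
        n = 200
        frames = []
        for i, pat in enumerate(PATTERNS):
            df = pd.DataFrame({
                "pattern": pat,
                "x1": rng.normal(10 * i, 1, n),
                "x2": rng.normal(-5 * i, 1, n),
            })
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        rep = train_pattern_classifier(data, features=("x1", "x2"), seed=0)
        assert rep.accuracy >= 0.95

    def test_shuffled_labels_hit_chance_level(self, default_pop, rng):
        df = default_pop.df.copy()
        df["pattern"] = rng.permutation(df["pattern"].to_numpy())
        rep = train_pattern_classifier(df, seed=1)
        se = np.sqrt(0.25 * 0.75 / 450)
        assert abs(rep.accuracy - 0.25) < 3 * se

    def test_importances_normalized(self, small_pop):
        rep = train_pattern_classifier(small_pop, seed=5, n_estimators=100)
        imp = rep.importances
        assert (imp["mean"] >= 0).all()
        assert imp["mean"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp["se"] >= 0).all()

    def test_single_class_rejected(self, small_pop):
        df = small_pop.df[small_pop.df.pattern == "Mixed"]
        with pytest.raises(ValueError, match="two"):
            train_pattern_classifier(df)

    def test_unknown_feature_rejected(self, small_pop):
        with pytest.raises(KeyError, match="nope"):
            train_pattern_classifier(small_pop, features=("nope",))


class TestRegressionMetrics:
    def test_hand_computed_rmse_and_mape(self):
        y = np.array([1.0, 2.0, 3.0])
        y_hat = np.array([1.0, 2.0, 4.0])
        assert rmse(y, y_hat) == pytest.approx(np.sqrt(1 / 3))
        assert mape_pct(y, y_hat) == pytest.approx(100 / 9)

    def test_constant_prediction_gives_zero_r2(self, rng):
        y = rng.normal(size=50)
        assert r_squared(y, np.full(50, y.mean())) == pytest.approx(0.0)

    def test_mape_excludes_zero_targets(self, caplog):
        with caplog.at_level("INFO"):
            value = mape_pct(np.array([0.0, 1.0]), np.array([5.0, 1.1]))
        assert value == pytest.approx(10.0)


class TestAdequacyRegression:
    def test_exact_linear_response_recovered(self, small_pop):
        df = small_pop.df
        y = 2.0 + 0.001 * df["energy_kcal"] + 0.05 * df["bmi_kg_m2"]
        rep = fit_adequacy_regression(small_pop, response=y.to_numpy(),
                                      predictors=("energy_kcal", "bmi_kg_m2"),
                                      seed=0)
        assert rep.r2 == pytest.approx(1.0, abs=1e-9)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.mape_pct == pytest.approx(0.0, abs=1e-7)
        assert rep.coefficients["energy_kcal"] == pytest.approx(0.001)

    def test_iron_adequacy_default_fit(self, default_pop):
        rep = fit_adequacy_regression(default_pop, seed=42)
        assert 0.0 < rep.r2 <= 1.0
        assert set(rep.per_pattern_r2) == set(PATTERNS)

    def test_collinear_design_named(self, small_pop):
        df = small_pop.df.copy()
        df["energy_copy"] = df["energy_kcal"]
        with pytest.raises(ValueError, match="energy"):
            fit_adequacy_regression(df, predictors=("energy_kcal", "energy_copy"))

    def test_constant_response_rejected(self, small_pop):
        with pytest.raises(ValueError, match="constant"):
            fit_adequacy_regression(small_pop,
                                    response=np.ones(len(small_pop.df)))
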