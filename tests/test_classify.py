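import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pallorscan import classify as cl
from pallorscan.errors import ModelStateError, TrainingError, ValidationError
from pallorscan.features import FEATURE_NAMES

from _oracles import auc_trapezoid


def hb_partition_oracle(sex, hb):
    """Independent statement of the Hb gradation table."""
    if hb < 10.5:
        return "anemic"
    upper = 13.5 if sex == "male" else 12.0
    return "moderate" if hb <= upper else "normal"


class TestHbLabeling:
    @pytest.mark.parametrize(
        "sex,hb,expected",
        [
            ("male", 9.0, "anemic"),
            ("female", 9.0, "anemic"),
            ("female", 11.0, "moderate"),
            ("male", 13.0, "moderate"),
            ("male", 14.0, "normal"),
            ("female", 12.5, "normal"),
            # boundary values fall in the moderate (closed) band
            ("male", 10.5, "moderate"),
            ("female", 10.5, "moderate"),
            ("male", 13.5, "moderate"),
            ("female", 12.0, "moderate"),
        ],
    )
    def test_gradation_table(self, sex, hb, expected):
        assert cl.label_from_hb(sex, hb) == expected

    def test_grid_partition_matches_oracle(self):
        for sex in ("male", "female"):
            for hb in np.round(np.arange(6.0, 18.0 + 1e-9, 0.05), 2):
                assert cl.label_from_hb(sex, float(hb)) == hb_partition_oracle(sex, hb)

    def test_implausible_values_rejected(self):
        for bad in (0.0, -1.0, 25.0, 40.0, float("nan")):
            with pytest.raises(ValidationError):
                cl.label_from_hb("male", bad)
        with pytest.raises(ValidationError):
            cl.label_from_hb("other", 12.0)


def separable_table(n_per_class=40, seed=0, spread=0.02):
    """Linearly separable 3-class feature table (class-coded red_pixel_pct)."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = {"anemic": 0.2, "moderate": 0.5, "normal": 0.8}
    for label, c in centers.items():
        for _ in range(n_per_class):
            base = rng.normal(0, 1, len(FEATURE_NAMES))
            row = dict(zip(FEATURE_NAMES, base))
            row["red_pixel_pct"] = rng.normal(c, spread)
            row["label"] = label
            rows.append(row)
    return pd.DataFrame(rows)


class TestTrainPredict:
    def test_separable_data_resubstitution_accuracy(self):
        table = separable_table(seed=1)
        model = cl.train_classifier(table, cl.MLPConfig(seed=1))
        X = table[list(FEATURE_NAMES)].to_numpy()
        acc = (model.predict(X) == table["label"].to_numpy()).mean()
        assert acc >= 0.99

    def test_missing_class_is_training_error(self):
        table = separable_table(seed=2)
        with pytest.raises(TrainingError):
            cl.train_classifier(table[table.label != "moderate"])

    def test_duplication_invariance(self):
        table = separable_table(n_per_class=30, seed=3)
        test = separable_table(n_per_class=10, seed=4)
        X = test[list(FEATURE_NAMES)].to_numpy()
        m1 = cl.train_classifier(table, cl.MLPConfig(seed=7))
        m2 = cl.train_classifier(
            pd.concat([table, table], ignore_index=True), cl.MLPConfig(seed=7)
        )
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_same_seed_identical_model(self):
        table = separable_table(seed=5)
        m1 = cl.train_classifier(table, cl.MLPConfig(seed=9))
        m2 = cl.train_classifier(table, cl.MLPConfig(seed=9))
        for a, b in zip(m1[-1].coefs_, m2[-1].coefs_):
            np.testing.assert_array_equal(a, b)

    def test_predict_probabilities_and_determinism(self):
        table = separable_table(seed=6)
        model = cl.train_classifier(table, cl.MLPConfig(seed=2))
        fv = table[list(FEATURE_NAMES)].iloc[0].to_numpy()
        label1, p1 = cl.predict_class(model, fv)
        label2, p2 = cl.predict_class(model, fv)
        assert label1 == label2 == table["label"].iloc[0]
        assert np.all(p1 >= 0) and abs(p1.sum() - 1) < 1e-6
        np.testing.assert_array_equal(p1, p2)

    def test_untrained_model_rejected(self):
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        raw = Pipeline([("scaler", StandardScaler()), ("mlp", MLPClassifier())])
        with pytest.raises(ModelStateError):
            cl.predict_class(raw, np.zeros(len(FEATURE_NAMES)))

    def test_model_round_trip(self, tmp_path):
        table = separable_table(seed=8)
        config = cl.MLPConfig(seed=3)
        model = cl.train_classifier(table, config)
        path = tmp_path / "model.joblib"
        cl.save_model(model, str(path), config)
        loaded = cl.load_model(str(path))
        X = table[list(FEATURE_NAMES)].to_numpy()
        np.testing.assert_array_equal(model.predict(X), loaded.predict(X))
        assert (tmp_path / "model.joblib.json").exists()


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["anemic"] * 3 + ["moderate"] * 4 + ["normal"] * 5
        cm = cl.confusion_matrix(labels, labels)
        assert np.trace(cm) == 12
        assert cm.sum() == 12
        np.testing.assert_array_equal(cm, np.diag([3, 4, 5]))

    def test_counting_example(self):
        truths = ["anemic", "anemic", "moderate", "normal"]
        preds = ["anemic", "moderate", "moderate", "normal"]
        cm = cl.confusion_matrix(truths, preds)
        np.testing.assert_array_equal(cm[0], [1, 1, 0])
        assert np.trace(cm) == 3

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            cl.confusion_matrix([], [])
        with pytest.raises(ValidationError):
            cl.confusion_matrix(["anemic"], ["anemic", "normal"])
        with pytest.raises(ValidationError):
            cl.confusion_matrix(["severe"], ["anemic"])


class TestMetrics:
    def test_perfect_matrix_scores_one(self):
        report = cl.classification_metrics(np.diag([10, 10, 10]))
        for cls in cl.CLASSES:
            for m in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
                assert report.per_class[cls][m] == 1.0
            assert report.per_class[cls]["fdr"] == 0.0
        assert report.overall_accuracy == 1.0

    def test_binary_style_worked_example(self):
        # anemic-vs-moderate block: TP=9, FN=1, FP=2, TN=8
        cm = np.array([[9, 1, 0], [2, 8, 0], [0, 0, 0]])
        with pytest.warns(UserWarning):  # the empty third class is undefined
            report = cl.classification_metrics(cm)
        anemic = report.per_class["anemic"]
        assert anemic["sensitivity"] == pytest.approx(0.9)
        assert anemic["specificity"] == pytest.approx(0.8)
        assert anemic["precision"] == pytest.approx(9 / 11, abs=1e-3)
        assert anemic["f1"] == pytest.approx(2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9), abs=1e-3)
        assert np.isnan(report.per_class["normal"]["precision"])

    def test_never_predicted_class_gives_nan_ppv(self):
        cm = np.array([[5, 5, 0], [0, 10, 0], [0, 10, 0]])
        with pytest.warns(UserWarning):
            report = cl.classification_metrics(cm)
        assert np.isnan(report.per_class["normal"]["ppv"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=9, max_size=9))
    def test_identities_on_random_matrices(self, entries):
        cm = np.asarray(entries).reshape(3, 3)
        if cm.sum() == 0:
            cm[0, 0] = 1
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cl.classification_metrics(cm)
        assert report.overall_accuracy == pytest.approx(np.trace(cm) / cm.sum())
        for cls in cl.CLASSES:
            ppv, fdr = report.per_class[cls]["ppv"], report.per_class[cls]["fdr"]
            if np.isfinite(ppv):
                assert ppv + fdr == pytest.approx(1.0)
            else:
                assert np.isnan(fdr)


class TestAuc:
    @staticmethod
    def _one_hot(labels):
        return np.array([[1.0 if c == l else 0.0 for c in cl.CLASSES] for l in labels])

    def test_perfect_and_reversed_scores(self):
        labels = ["anemic"] * 5 + ["moderate"] * 5 + ["normal"] * 5
        probs = self._one_hot(labels)
        assert all(v == 1.0 for v in cl.roc_auc_ovr(labels, probs).values())
        reversed_probs = 1.0 - probs
        reversed_probs /= reversed_probs.sum(axis=1, keepdims=True)
        assert all(v == 0.0 for v in cl.roc_auc_ovr(labels, reversed_probs).values())

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2024)
        labels = [cl.CLASSES[i] for i in rng.integers(0, 3, size=2000)]
        probs = rng.uniform(size=(2000, 3))
        probs /= probs.sum(axis=1, keepdims=True)
        for v in cl.roc_auc_ovr(labels, probs).values():
            assert v == pytest.approx(0.5, abs=0.05)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.booleans(), min_size=4, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    def test_rank_formulation_equals_trapezoid_sweep(self, is_pos, seed):
        if not (any(is_pos) and not all(is_pos)):
            is_pos = [True, False] + is_pos[2:]
        rng = np.random.default_rng(seed)
        n = len(is_pos)
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        labels = ["anemic" if p else "normal" for p in is_pos]
        probs = np.zeros((n, 3))
        probs[:, 0] = scores
        probs[:, 2] = 1 - scores
        auc = cl.roc_auc_ovr(labels, probs)["anemic"]
        assert auc == pytest.approx(auc_trapezoid(is_pos, scores), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = [cl.CLASSES[i] for i in rng.integers(0, 3, size=200)]
        probs = rng.uniform(size=(200, 3))
        ours = cl.roc_auc_ovr(labels, probs)
        for i, cls in enumerate(cl.CLASSES):
            ref = roc_auc_score([l == cls for l in labels], probs[:, i])
            assert ours[cls] == pytest.approx(ref, abs=1e-12)

    def test_single_class_truths_rejected(self):
        with pytest.raises(ValidationError):
            cl.roc_auc_ovr(["anemic"] * 4, np.full((4, 3), 1 / 3))


class TestEvaluateSplit:
    def test_study_scale_split_sizes(self):
        labels = ["anemic"] * 132 + ["moderate"] * 169 + ["normal"] * 310
        train, test = cl.stratified_split(labels, 0.10, seed=0)
        assert len(train) == 550 and len(test) == 61
        test_labels = np.asarray(labels)[test]
        assert (test_labels == "anemic").sum() == 13
        assert (test_labels == "moderate").sum() == 17
        assert (test_labels == "normal").sum() == 31

    def test_separable_resubstitution_close_to_heldout(self):
        table = separable_table(n_per_class=60, seed=10)
        result = cl.evaluate_split(table, cl.MLPConfig(seed=10))
        assert result.resubstitution.overall_accuracy >= result.heldout.overall_accuracy - 0.05
        assert result.heldout.overall_accuracy >= 0.95

    def test_determinism(self):
        table = separable_table(n_per_class=30, seed=11)
        r1 = cl.evaluate_split(table, cl.MLPConfig(seed=4))
        r2 = cl.evaluate_split(table, cl.MLPConfig(seed=4))
        np.testing.assert_array_equal(r1.cm_heldout, r2.cm_heldout)
        assert r1.heldout.to_dict() == r2.heldout.to_dict()
        assert r1.auc_heldout == r2.auc_heldout

    def test_tiny_class_rejected(self):
        labels = ["anemic", "moderate", "moderate", "normal", "normal"]
        with pytest.raises(ValidationError):
            cl.stratified_split(labels, 0.10, seed=0)
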