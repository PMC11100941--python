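"""Label binning, CORAL ordinal head, metrics, and latent-space traversal."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from kneeshape.clinical import (
    ClassifierSpec,
    ClinicalLabelRecord,
    MOAKS_REGIONS,
    bin_labels,
    coral_loss,
    coral_predict,
    interpolate_latents,
    mean_latent_by_stratum,
    metrics,
    train_classifier,
    traverse_classifier,
)


def _record(kl=0, osteo=0, thin=0, hole=0):
    r = ClinicalLabelRecord(shape_id="t", kl=kl)
    r.osteophyte_raw = {MOAKS_REGIONS[0]: osteo}
    r.thinning_raw = {MOAKS_REGIONS[0]: thin}
    r.hole_raw = {MOAKS_REGIONS[0]: hole}
    return r


class TestBinLabels:
    @pytest.mark.parametrize("kl,oa", [(0, 0), (1, 0), (2, 1), (3, 1), (4, 1)])
    def test_oa_diagnosis_threshold(self, kl, oa):
        assert bin_labels(_record(kl=kl)).oa == oa

    @pytest.mark.parametrize("raw,binned", [(0, 0), (1, 1), (2, 2), (3, 2)])
    def test_osteophyte_binning(self, raw, binned):
        assert bin_labels(_record(osteo=raw)).osteophyte_binned[MOAKS_REGIONS[0]] == binned

    @pytest.mark.parametrize("raw,binary", [(0, 0), (1, 0), (2, 1), (3, 1)])
    def test_thinning_binarization(self, raw, binary):
        assert bin_labels(_record(thin=raw)).thinning_binary[MOAKS_REGIONS[0]] == binary

    @pytest.mark.parametrize("raw,binary", [(0, 0), (1, 1), (2, 1), (3, 1)])
    def test_hole_binarization(self, raw, binary):
        assert bin_labels(_record(hole=raw)).hole_binary[MOAKS_REGIONS[0]] == binary

    def test_out_of_range_grades_rejected(self):
        with pytest.raises(ValueError, match="KL"):
            bin_labels(_record(kl=5))
        with pytest.raises(ValueError, match="osteophyte"):
            bin_labels(_record(osteo=4))


class TestCoral:
    def test_strongly_negative_logits_predict_zero_with_tiny_loss(self):
        logits = np.full(4, -20.0)
        assert coral_predict(logits)[0] == 0
        assert coral_loss(logits, 0, n_classes=5) < 1e-6

    def test_count_over_threshold_rule(self):
        # sigmoids (0.9, 0.8, 0.4, 0.1) -> two thresholds exceeded -> grade 2
        sig = np.array([0.9, 0.8, 0.4, 0.1])
        logits = np.log(sig / (1 - sig))
        assert coral_predict(logits)[0] == 2

    @pytest.mark.parametrize("grade", range(5))
    def test_perfect_cumulative_targets_recover_every_grade(self, grade):
        targets = (grade > np.arange(4)).astype(float)
        logits = np.where(targets > 0, 20.0, -20.0)
        assert coral_predict(logits)[0] == grade
        assert coral_loss(logits, grade, n_classes=5) < 1e-6

    def test_shared_weight_head_cumulative_monotonicity(self):
        # shared weights + ordered biases give non-increasing cumulative probs
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 8)
        biases = np.sort(rng.normal(0, 1, 4))[::-1]
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            p = 1 / (1 + np.exp(-(w @ x + biases)))
            assert (np.diff(p) <= 1e-12).all()

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError):
            coral_loss(np.zeros(4), 5, n_classes=5)


class TestMetrics:
    def test_perfect_ordinal_predictions(self):
        y = np.array([0, 1, 2, 3, 4, 2, 1])
        rep = metrics(y, y, task="ordinal")
        assert rep["kappa"] == pytest.approx(1.0)
        assert rep["accuracy"] == 1.0

    def test_constant_predictor_kappa_zero(self):
        labels = np.array([0, 1, 2, 2, 1, 0, 2, 1])
        preds = np.full_like(labels, 1)
        rep = metrics(preds, labels, task="ordinal")
        assert rep["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_kappa_matches_manual_confusion_matrix(self):
        # manual computation on a fixed 3x3 confusion matrix
        labels = np.array([0] * 10 + [1] * 10 + [2] * 10)
        preds = np.array([0] * 8 + [1] * 2 + [1] * 7 + [2] * 3 + [2] * 9 + [0] * 1)
        K = 3
        cm = np.zeros((K, K))
        for t, p in zip(labels, preds):
            cm[t, p] += 1
        w = np.array([[(i - j) ** 2 for j in range(K)] for i in range(K)]) / (K - 1) ** 2
        expected_cm = np.outer(cm.sum(1), cm.sum(0)) / cm.sum()
        manual = 1 - (w * cm).sum() / (w * expected_cm).sum()
        rep = metrics(preds, labels, task="ordinal")
        assert rep["kappa"] == pytest.approx(manual, abs=1e-12)

    def test_binary_report_fields(self):
        labels = np.array([0, 0, 1, 1, 1, 0])
        probs = np.array([0.1, 0.4, 0.9, 0.6, 0.8, 0.2])
        rep = metrics((probs > 0.5).astype(int), labels, task="binary", probabilities=probs)
        assert rep["auroc"] == pytest.approx(1.0)
        assert rep["f1"] == 1.0
        assert rep["auprc"] == pytest.approx(1.0)

    def test_single_class_labels_give_missing_auroc(self):
        labels = np.zeros(4, dtype=int)
        rep = metrics(labels, labels, task="binary", probabilities=np.full(4, 0.2))
        assert np.isnan(rep["auroc"]) and np.isnan(rep["auprc"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.array([]), np.array([]), task="binary")


class TestTrainClassifier:
    @staticmethod
    def _separable(n=200, dim=8, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n, dim))
        y = (x[:, 1] > 0).astype(int)
        idx = rng.permutation(n)
        return x, y, (idx[60:], idx[:60])

    def test_logistic_head_separates_sign_of_one_component(self):
        x, y, split = self._separable()
        spec = ClassifierSpec(head="logistic", task="binary")
        fitted = train_classifier(x, y, spec, split)
        assert fitted.validation_score > 0.99

    def test_mlp_head_beats_chance_on_separable_data(self):
        x, y, split = self._separable()
        spec = ClassifierSpec(
            head="mlp", task="binary",
            depths=(2,), widths=(32,), dropouts=(0.2,), lrs=(1e-3,), batches=(64,), epochs=60,
        )
        fitted = train_classifier(x, y, spec, split, seed=1)
        assert fitted.validation_score > 0.9

    def test_shuffled_labels_near_chance(self):
        x, y, split = self._separable(seed=2)
        y = np.random.default_rng(3).permutation(y)
        spec = ClassifierSpec(head="logistic", task="binary")
        fitted = train_classifier(x, y, spec, split)
        assert abs(fitted.validation_score - 0.5) < 0.15

    def test_ordinal_mlp_learns_monotone_grades(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (300, 6))
        y = np.clip(np.digitize(x[:, 0], [-1.0, 0.0, 1.0]), 0, 3)
        idx = rng.permutation(len(x))
        split = (idx[80:], idx[:80])
        spec = ClassifierSpec(
            head="mlp", task="ordinal", n_classes=4,
            depths=(2,), widths=(32,), dropouts=(0.2,), lrs=(1e-2,), batches=(64,), epochs=80,
        )
        fitted = train_classifier(x, y, spec, split, seed=5)
        assert fitted.validation_score > 0.5  # quadratic kappa well above chance

    def test_same_seed_same_winner(self):
        x, y, split = self._separable(seed=6)
        spec = ClassifierSpec(
            head="mlp", task="binary",
            depths=(2,), widths=(16, 32), dropouts=(0.2,), lrs=(1e-3,), batches=(64,), epochs=30,
        )
        a = train_classifier(x, y, spec, split, seed=7)
        b = train_classifier(x, y, spec, split, seed=7)
        assert a.config == b.config
        assert a.validation_score == b.validation_score

    def test_single_class_split_rejected(self):
        x = np.zeros((10, 3))
        y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError):
            train_classifier(x, y, ClassifierSpec(head="logistic"), (np.arange(8), np.arange(8, 10)))


class TestInterpretability:
    def test_interpolation_endpoints_and_midpoint(self):
        z_a, z_b = np.arange(4.0), np.arange(4.0) * -1
        path = interpolate_latents(z_a, z_b, 3)
        np.testing.assert_array_equal(path[0], z_a)
        np.testing.assert_array_equal(path[-1], z_b)
        np.testing.assert_allclose(path[1], (z_a + z_b) / 2)

    def test_traversal_probability_strictly_monotone(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (200, 5))
        y = (x @ np.array([1.0, -2.0, 0.5, 0.0, 0.0]) > 0).astype(int)
        clf = LogisticRegression().fit(x, y)
        direction = clf.coef_.ravel()
        z = rng.normal(0, 1, 5)
        steps = np.linspace(-3, 3, 13)
        path = traverse_classifier(z, direction, steps)
        probs = clf.predict_proba(path)[:, 1]
        assert (np.diff(probs) > 0).all()

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            traverse_classifier(np.zeros(4), np.zeros(4), np.array([0.0, 1.0]))

    def test_stratum_means(self):
        lat = np.array([[0.0, 0], [2, 2], [4, 4]])
        strata = np.array([0, 4, 4])
        np.testing.assert_array_equal(mean_latent_by_stratum(lat, strata, 4), [3, 3])
        with pytest.raises(ValueError):
            mean_latent_by_stratum(lat, strata, 2)
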