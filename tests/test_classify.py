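"""Normalisation, one-vs-rest linear SVMs, under-sampling, model I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest

from icegait.classify import (
    HEEL_CLASSES,
    TOE_CLASSES,
    Normalization,
    OvrLinearSvm,
    SlipLabel,
    TrainedSlipModel,
    fit_taxonomy_classifier,
    normalize_fit_apply,
    slip_disjunction,
    train_ovr_linear_svm,
    undersample,
)
from icegait.config import DEFAULT_CONFIG


class TestNormalization:
    def test_zscore_known_values(self):
        train = np.array([[3.0], [7.0]])  # mean 5, sd 2
        _, z, _ = normalize_fit_apply(train, np.array([[7.0]]))
        assert z[0, 0] == pytest.approx(1.0)

    def test_constant_column_maps_to_zero(self):
        train = np.full((10, 2), 4.0)
        train[:, 1] = np.arange(10)
        z, _, _ = normalize_fit_apply(train, train)
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_train_applied_to_itself_is_standardised(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 2, (200, 4))
        z, _, _ = normalize_fit_apply(X, X)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_fit_apply(np.zeros((5, 3)), np.zeros((5, 4)))


class TestSlipDecision:
    def test_disjunction_over_all_sixteen_combinations(self):
        for bts, fts, bhs, fhs in itertools.product([False, True], repeat=4):
            assert slip_disjunction(bts, fts, bhs, fhs) == (bts or fts or bhs or fhs)

    @pytest.mark.parametrize(
        "toe,heel,expected",
        [("NTS", "NHS", False), ("BTS", "NHS", True), ("NTS", "FHS", True),
         ("BTS", "BHS", True), ("FTS", "FHS", True)],
    )
    def test_label_slip_flag(self, toe, heel, expected):
        assert SlipLabel(toe_class=toe, heel_class=heel).slip is expected

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            SlipLabel(toe_class="XXX")


def blobs(n_per_class=60, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = {"NTS": (0, 0), "BTS": (sep, 0), "FTS": (0, sep)}
    X, y = [], []
    for cls, c in centers.items():
        X.append(rng.normal(c, 1.0, (n_per_class, 2)))
        y += [cls] * n_per_class
    return np.vstack(X), np.asarray(y)


class TestOvrSvm:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, y = blobs(sep=8.0)
        model = train_ovr_linear_svm(X, y, TOE_CLASSES, "NTS", C=1.0)
        assert (model.predict(X) == y).all()

    def test_permuted_labels_score_at_chance(self):
        """Training on shuffled labels gives held-out accuracy near 1/3."""
        X, y = blobs(n_per_class=150, sep=6.0)
        rng = np.random.default_rng(1)
        y_shuf = rng.permutation(y)
        model = train_ovr_linear_svm(X[:300], y_shuf[:300], TOE_CLASSES, "NTS", C=1.0)
        acc = float(np.mean(model.predict(X[300:]) == y_shuf[300:]))
        assert abs(acc - 1 / 3) < 0.15

    def test_duplicated_training_set_gives_same_rule(self):
        X, y = blobs()
        m1 = train_ovr_linear_svm(X, y, TOE_CLASSES, "NTS", C=1.0)
        m2 = train_ovr_linear_svm(
            np.vstack([X, X]), np.concatenate([y, y]), TOE_CLASSES, "NTS", C=1.0
        )
        grid = np.array(np.meshgrid(np.linspace(-3, 9, 25), np.linspace(-3, 9, 25)))
        pts = grid.reshape(2, -1).T
        assert np.mean(m1.predict(pts) == m2.predict(pts)) > 0.99

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["NTS"] * 10)
        with pytest.raises(ValueError):
            train_ovr_linear_svm(X, y, TOE_CLASSES, "NTS")

    def test_training_reproducible_bit_for_bit(self):
        X, y = blobs(seed=5)
        m1 = train_ovr_linear_svm(X, y, TOE_CLASSES, "NTS", C=1.0, seed=3)
        m2 = train_ovr_linear_svm(X, y, TOE_CLASSES, "NTS", C=1.0, seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.platt, m2.platt)

    def test_tie_breaks_to_no_slip_class(self):
        model = OvrLinearSvm(
            classes=TOE_CLASSES, no_slip_class="NTS",
            weights=np.zeros((3, 2)), intercepts=np.zeros(3),
            platt=np.tile([-1.0, 0.0], (3, 1)), C=1.0, score="margin",
        )
        assert model.predict(np.zeros((1, 2)))[0] == "NTS"

    def test_platt_scores_are_probability_like(self):
        X, y = blobs(sep=8.0)
        model = train_ovr_linear_svm(X, y, TOE_CLASSES, "NTS", C=1.0)
        s = model.scores(X)
        assert np.all((s >= 0) & (s <= 1))
        # confident region: the true class score dominates
        assert s[0, 0] > 0.5


class TestUndersample:
    def test_majority_downsampled_to_total_slip_count(self):
        labels = np.array(["NHS"] * 1000 + ["BHS"] * 100 + ["FHS"] * 150)
        idx = undersample(labels, "NHS", seed=0)
        sub = labels[idx]
        assert (sub == "NHS").sum() == 250
        assert (sub == "BHS").sum() == 100
        assert (sub == "FHS").sum() == 150

    def test_balanced_input_unchanged(self):
        labels = np.array(["NHS"] * 100 + ["BHS"] * 100)
        idx = undersample(labels, "NHS", seed=0)
        assert len(idx) == 200

    def test_deterministic_given_seed_and_repeat(self):
        labels = np.array(["NHS"] * 500 + ["BHS"] * 50)
        a = undersample(labels, "NHS", seed=9, repeat_index=2)
        b = undersample(labels, "NHS", seed=9, repeat_index=2)
        np.testing.assert_array_equal(a, b)
        c = undersample(labels, "NHS", seed=9, repeat_index=3)
        assert not np.array_equal(a, c)


class TestTrainedModel:
    @staticmethod
    def fitted_model(small_dataset):
        from icegait.features import HEEL_CLASSIFIER_FEATURES, TOE_CLASSIFIER_FEATURES

        table, _ = small_dataset
        cc = DEFAULT_CONFIG.classifier
        models = {}
        for tax, classes, ns, ids, col in (
            ("toe", TOE_CLASSES, "NTS", TOE_CLASSIFIER_FEATURES, "toe_class"),
            ("heel", HEEL_CLASSES, "NHS", HEEL_CLASSIFIER_FEATURES, "heel_class"),
        ):
            cols = [f"f{i}" for i in ids]
            idx = undersample(table[col].to_numpy(), ns, seed=0)
            sub = table.iloc[idx]
            n_val = max(int(0.2 * len(sub)), 3)
            model, norm, _ = fit_taxonomy_classifier(
                sub[cols].to_numpy(float)[n_val:], sub[col].to_numpy()[n_val:],
                sub[cols].to_numpy(float)[:n_val], sub[col].to_numpy()[:n_val],
                classes, ns, cc, seed=0,
            )
            models[tax] = (model, norm)
        return TrainedSlipModel(
            toe=models["toe"][0], heel=models["heel"][0],
            toe_norm=models["toe"][1], heel_norm=models["heel"][1],
        )

    def test_json_roundtrip_preserves_predictions(self, small_dataset, tmp_path):
        table, _ = small_dataset
        model = self.fitted_model(small_dataset)
        pred1 = model.predict_frame(table)
        path = tmp_path / "model.json"
        model.save(path)
        model2 = TrainedSlipModel.load(path)
        pred2 = model2.predict_frame(table)
        pd.testing.assert_frame_equal(pred1, pred2)

    def test_predictions_follow_eq5_disjunction(self, small_dataset):
        table, _ = small_dataset
        model = self.fitted_model(small_dataset)
        pred = model.predict_frame(table)
        expected = (pred.toe_class != "NTS") | (pred.heel_class != "NHS")
        np.testing.assert_array_equal(pred.slip.to_numpy(), expected.to_numpy())
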