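import warnings

import numpy as np
import pandas as pd
import pytest

from spastiq.evaluation import (
    EvaluationConfig,
    cohen_kappa,
    digitize_mas,
    fit_pca,
    k_trial_protocol,
    loso_evaluate,
    pearson_r,
    r_squared,
    rmse,
    round_to_levels,
    sample_k_trials,
)
from spastiq.exceptions import DegenerateFitError, InputError, UnsupportedLabelError
from spastiq.features import FEATURE_NAMES


class TestDigitizeMas:
    @pytest.mark.parametrize("label,value", [("0", 0.0), ("1", 1.0), ("1+", 1.5), ("2", 2.0)])
    def test_supported_labels(self, label, value):
        assert digitize_mas(label) == value

    @pytest.mark.parametrize("label", ["3", "4", "2+", ""])
    def test_out_of_cohort_labels_rejected(self, label):
        with pytest.raises(UnsupportedLabelError):
            digitize_mas(label)


class TestRounding:
    def test_ties_go_to_higher_level(self):
        np.testing.assert_array_equal(
            round_to_levels(np.array([0.5, 1.25, 1.75, -0.4, 2.9])),
            [1.0, 1.5, 2.0, 0.0, 2.0],
        )


class TestMetrics:
    def test_r_squared_examples(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0
        assert r_squared(y, np.array([0.0, 1.0, 1.0])) == pytest.approx(0.5)

    def test_r_squared_constant_reference_rejected(self):
        with pytest.raises(DegenerateFitError):
            r_squared(np.ones(3), np.zeros(3))

    def test_rmse_examples(self):
        y = np.array([0.0, 2.0])
        assert rmse(y, y) == 0.0
        assert rmse(y, y + 0.7) == pytest.approx(0.7)
        assert rmse(y, np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_kappa_identical_vectors(self):
        a = np.array([0.0, 1.0, 1.5, 2.0, 1.0])
        assert cohen_kappa(a, a) == 1.0

    def test_kappa_hand_confusion_table(self):
        # [[25, 5], [10, 60]]: p_o = 0.85, p_e = 0.56 -> 0.29/0.44
        a = np.repeat([0, 0, 1, 1], [25, 5, 10, 60])
        b = np.repeat([0, 1, 0, 1], [25, 5, 10, 60])
        assert cohen_kappa(a, b) == pytest.approx(0.29 / 0.44)

    def test_kappa_chance_level_is_zero(self):
        a = np.zeros(100)
        b = np.repeat([0.0, 1.0], 50)
        assert cohen_kappa(a, b) == pytest.approx(0.0)

    def test_pearson_perfect_line(self):
        y = np.arange(10, dtype=float)
        assert pearson_r(y, 3 * y + 1) == pytest.approx(1.0)


class TestPca:
    def test_low_rank_data_keeps_three_components(self, rng):
        basis = rng.normal(size=(3, 20))
        scores = rng.normal(size=(500, 3)) * [5.0, 4.0, 3.0]
        F = scores @ basis + rng.normal(scale=1e-4, size=(500, 20))
        state = fit_pca(F, var_target=0.95)
        assert state.n_components == 3

    def test_full_variance_keeps_all_nondegenerate_components(self, rng):
        F = rng.normal(size=(50, 6))
        assert fit_pca(F, var_target=1.0).n_components == 6

    def test_transform_inverse_transform_identity(self, rng):
        F = rng.normal(size=(100, 8))
        state = fit_pca(F, var_target=1.0)
        np.testing.assert_allclose(state.inverse_transform(state.transform(F)), F,
                                   atol=1e-9)

    def test_constant_column_warns_and_survives(self, rng):
        F = rng.normal(size=(50, 5))
        F[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            state = fit_pca(F)
        assert np.isfinite(state.transform(F)).all()

    def test_components_orthonormal(self, rng):
        state = fit_pca(rng.normal(size=(200, 10)))
        gram = state.components @ state.components.T
        np.testing.assert_allclose(gram, np.eye(state.n_components), atol=1e-9)


def _linear_table(rng, n_subjects=6, windows_per_subject=40):
    """Windows whose features are an exact linear function of the MAS score."""
    rows = []
    levels = [0.0, 1.0, 1.5, 2.0]
    direction = rng.normal(size=20)
    for s in range(n_subjects):
        mas = levels[s % len(levels)]
        for w in range(windows_per_subject):
            f = mas * direction + 0.001 * rng.normal(size=20)
            row = {"subject_id": f"S{s}", "trial_id": f"S{s}_t{w % 4}",
                   "window_index": w, "mas_numeric": mas,
                   "velocity_class": "fast", "group": "patient"}
            row.update(zip(FEATURE_NAMES, f))
            rows.append(row)
    return pd.DataFrame(rows)


class TestLoso:
    def test_exact_linear_features_recovered(self, rng):
        # two subjects per level so every fold interpolates within coverage
        table = _linear_table(rng, n_subjects=8)
        report = loso_evaluate(table)
        assert report.r2 > 0.999
        assert report.rmse < 0.01

    def test_two_subjects_two_folds(self, rng):
        table = _linear_table(rng, n_subjects=2)
        report = loso_evaluate(table)
        assert len(report.subjects) == 2

    def test_predictions_clipped_to_score_range(self, rng):
        table = _linear_table(rng)
        report = loso_evaluate(table)
        assert (report.subjects["y_hat"] >= 0).all()
        assert (report.subjects["y_hat"] <= 2).all()

    def test_single_subject_rejected(self, rng):
        table = _linear_table(rng, n_subjects=1)
        with pytest.raises(InputError):
            loso_evaluate(table)


class TestKTrialProtocol:
    def test_same_seed_reproduces_reports(self, rng):
        table = _linear_table(rng)
        a = k_trial_protocol(table, k=2, repeats=2, seed=5)
        b = k_trial_protocol(table, k=2, repeats=2, seed=5)
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra.subjects, rb.subjects)

    def test_k_equal_to_available_trials_is_identity(self, rng):
        table = _linear_table(rng)
        full = sorted(table["trial_id"].unique())
        sub = sample_k_trials(table, k=4, rng=np.random.default_rng(0))
        assert sorted(sub["trial_id"].unique()) == full

    def test_subsets_are_nested_across_k(self, rng):
        table = _linear_table(rng)
        s2 = sample_k_trials(table, 2, np.random.default_rng(7))
        s3 = sample_k_trials(table, 3, np.random.default_rng(7))
        assert set(s2["trial_id"]) <= set(s3["trial_id"])

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(InputError):
            k_trial_protocol(_linear_table(rng), k=0)
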