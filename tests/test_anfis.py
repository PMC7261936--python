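import numpy as np
import pytest

from spastiq.anfis import (
    AnfisModel,
    ClusteringConfig,
    FuzzyRule,
    GaussianMF,
    firing_strengths,
    init_structure,
    membership,
    normalize,
    predict,
    subtractive_cluster,
    train_consequents,
)
from spastiq.exceptions import ConfigError, InputError


def _two_rule_model():
    r1 = FuzzyRule(
        premise=[GaussianMF(0.0, 1.0), GaussianMF(1.0, 0.5)],
        coefficients=np.array([1.0, -2.0]),
        bias=0.5,
    )
    r2 = FuzzyRule(
        premise=[GaussianMF(2.0, 0.8), GaussianMF(-1.0, 1.2)],
        coefficients=np.array([0.3, 0.7]),
        bias=-1.0,
    )
    return AnfisModel(rules=[r1, r2], n_inputs=2)


class TestMembership:
    def test_center_gives_one(self):
        assert membership(GaussianMF(3.0, 0.7), 3.0) == 1.0

    def test_one_width_offset(self):
        assert membership(GaussianMF(0.0, 2.0), 2.0) == pytest.approx(np.exp(-0.5))

    def test_symmetry(self):
        mf = GaussianMF(1.0, 0.4)
        assert membership(mf, 1.7) == pytest.approx(membership(mf, 0.3))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError):
            GaussianMF(0.0, 0.0)


class TestForwardPass:
    def test_single_rule_single_input_strength_is_membership(self):
        rule = FuzzyRule([GaussianMF(0.5, 0.3)], np.array([0.0]), 0.0)
        model = AnfisModel([rule], n_inputs=1)
        w = firing_strengths(model, np.array([0.9]))
        assert w[0] == pytest.approx(membership(rule.premise[0], 0.9))

    def test_strength_is_one_at_premise_centers(self):
        model = _two_rule_model()
        w = firing_strengths(model, np.array([0.0, 1.0]))
        assert w[0] == pytest.approx(1.0)

    def test_strengths_match_manual_product(self):
        model = _two_rule_model()
        x = np.array([0.4, -0.2])
        w = firing_strengths(model, x)
        for i, rule in enumerate(model.rules):
            manual = np.prod([membership(mf, xv) for mf, xv in zip(rule.premise, x)])
            assert w[i] == pytest.approx(manual, rel=1e-12)

    def test_normalize_examples(self):
        np.testing.assert_allclose(normalize(np.array([1.0, 1.0])), [0.5, 0.5])
        np.testing.assert_allclose(normalize(np.array([2.0, 0.0])), [1.0, 0.0])
        with pytest.raises(InputError):
            normalize(np.array([0.0, 0.0]))

    def test_one_rule_prediction_is_linear_function(self):
        rule = FuzzyRule([GaussianMF(0.0, 1.0), GaussianMF(0.0, 1.0)],
                         np.array([2.0, -1.0]), 0.25)
        model = AnfisModel([rule], n_inputs=2)
        for x in np.random.default_rng(4).normal(size=(20, 2)):
            assert predict(model, x) == pytest.approx(2 * x[0] - x[1] + 0.25, rel=1e-12)

    def test_identical_consequents_collapse_to_that_function(self):
        model = _two_rule_model()
        for rule in model.rules:
            rule.coefficients = np.array([1.5, 0.5])
            rule.bias = -0.3
        for x in np.random.default_rng(5).normal(size=(20, 2)):
            assert predict(model, x) == pytest.approx(1.5 * x[0] + 0.5 * x[1] - 0.3,
                                                      rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            predict(_two_rule_model(), np.array([1.0]))


class TestSubtractiveClustering:
    def test_single_point_is_sole_center(self):
        X = np.array([[0.3, 0.7]])
        centers = subtractive_cluster(X)
        np.testing.assert_array_equal(centers, X)

    def test_identical_points_give_one_center(self):
        X = np.tile([1.0, 2.0], (20, 1))
        assert subtractive_cluster(X).shape == (1, 2)

    def test_two_separated_blobs_give_two_centers(self, rng):
        a = rng.normal([0.0, 0.0], 0.02, size=(60, 2))
        b = rng.normal([5.0, 5.0], 0.02, size=(60, 2))
        centers = subtractive_cluster(np.vstack([a, b]))
        assert centers.shape[0] == 2
        dists = np.linalg.norm(
            centers[:, None, :] - np.array([[0.0, 0.0], [5.0, 5.0]])[None], axis=2
        )
        assert dists.min(axis=1).max() < 0.1

    def test_permutation_invariant_center_set(self, rng):
        X = np.vstack([
            rng.normal([0, 0], 0.05, size=(40, 2)),
            rng.normal([3, 3], 0.05, size=(40, 2)),
        ])
        c1 = subtractive_cluster(X)
        perm = rng.permutation(len(X))
        c2 = subtractive_cluster(X[perm])
        assert {tuple(np.round(c, 6)) for c in c1} == {tuple(np.round(c, 6)) for c in c2}

    def test_never_more_centers_than_points(self, rng):
        X = rng.normal(size=(7, 3))
        assert subtractive_cluster(X).shape[0] <= 7


class TestStructureAndTraining:
    def test_one_rule_per_center_with_full_premise(self, rng):
        X = np.vstack([
            rng.normal(0.0, 0.05, size=(50, 9)),
            rng.normal(1.0, 0.05, size=(50, 9)),
        ])
        model = init_structure(X)
        assert model.n_inputs == 9
        assert len(model.rules) >= 2
        assert all(len(r.premise) == 9 for r in model.rules)

    def test_consequent_recovery_on_self_generated_data(self, rng):
        X = rng.uniform(-1, 1, size=(300, 3))
        true = init_structure(X, ClusteringConfig(radius=0.5))
        rng2 = np.random.default_rng(99)
        for rule in true.rules:
            rule.coefficients = rng2.normal(size=3)
            rule.bias = float(rng2.normal())
        y = predict(true, X)
        fresh = AnfisModel.from_json(true.to_json())
        for rule in fresh.rules:
            rule.coefficients = np.zeros(3)
            rule.bias = 0.0
        train_consequents(fresh, X, y)
        for r_true, r_fit in zip(true.rules, fresh.rules):
            np.testing.assert_allclose(r_fit.coefficients, r_true.coefficients, atol=1e-7)
            assert r_fit.bias == pytest.approx(r_true.bias, abs=1e-7)

    def test_constant_target_gives_zero_slopes_and_bias_k(self, rng):
        X = rng.normal(size=(200, 2))
        model = init_structure(X)
        train_consequents(model, X, np.full(200, 1.5))
        for rule in model.rules:
            np.testing.assert_allclose(rule.coefficients, 0.0, atol=1e-8)
            assert rule.bias == pytest.approx(1.5, abs=1e-8)

    def test_hybrid_training_residual_never_increases(self, rng):
        X = rng.normal(size=(150, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        model = init_structure(X)
        train_consequents(model, X, y, epochs=5, mode="hybrid")
        hist = model.training_meta["history"]
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_serialization_round_trip_is_exact(self):
        model = _two_rule_model()
        back = AnfisModel.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        np.testing.assert_array_equal(back.centers, model.centers)
        np.testing.assert_array_equal(back.widths, model.widths)
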