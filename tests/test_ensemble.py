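import numpy as np
import pytest

from pafscreen.ensemble import (
    BaseLearnerSpec,
    _update_weights,
    adaboost_predict,
    adaboost_train,
    bagging_predict,
    bagging_train,
    stacking_predict,
    stacking_train,
    train_cart,
)
from pafscreen.errors import ConfigurationError


def _toy_data(n=60, seed=0, separation=2.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.normal(size=(n, 4))
    X[:half, 0] += separation
    y = np.array(["PAF"] * half + ["normal"] * half)
    return X, y


class TestCART:
    def test_separable_data_perfect_training_accuracy(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["normal", "normal", "PAF", "PAF"])
        tree = train_cart(X, y, BaseLearnerSpec(complexity_parameter=0.01))
        assert np.all(tree.predict(X) == y)

    def test_huge_cp_prunes_to_majority_predictor(self):
        X, y = _toy_data(seed=1)
        y = np.array(["PAF"] * 40 + ["normal"] * 20)
        tree = train_cart(X, y, BaseLearnerSpec(complexity_parameter=10.0))
        assert tree.get_depth() == 0
        assert np.all(tree.predict(X) == "PAF")

    def test_sample_weights_dominate(self):
        # concentrating nearly all weight on one point makes the tree
        # predict that point's class in its region (weighted-impurity oracle:
        # any split must serve the heavy point)
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["normal", "normal", "PAF", "normal"])
        w = np.array([1e-6, 1e-6, 1.0, 1e-6])
        tree = train_cart(X, y, BaseLearnerSpec(complexity_parameter=0.01), sample_weight=w)
        assert tree.predict([[2.0]])[0] == "PAF"

    def test_single_class_flagged(self):
        X = np.ones((4, 2))
        y = np.array(["PAF"] * 4)
        with pytest.warns(UserWarning):
            tree = train_cart(X, y)
        assert np.all(tree.predict(X) == "PAF")


class TestBagging:
    def test_members_satisfy_accuracy_condition(self):
        X, y = _toy_data()
        model = bagging_train(X, y, n_members=20, seed=0)
        assert model.n_members == 20 and len(model.members) == 20
        assert np.all(model.diagnostics["member_train_accuracy"] > 0.5)

    def test_single_member_equals_its_prediction(self):
        X, y = _toy_data(seed=2)
        model = bagging_train(X, y, n_members=1, seed=3)
        labels, score = bagging_predict(model, X)
        assert np.all(labels == model.members[0].predict(X))
        assert set(np.unique(score)) <= {0.0, 1.0}

    def test_vote_fraction_matches_brute_force(self):
        X, y = _toy_data(seed=4)
        model = bagging_train(X, y, n_members=15, seed=5)
        _, score = bagging_predict(model, X)
        brute = np.mean(
            [m.predict(X) == "PAF" for m in model.members], axis=0
        )
        assert np.allclose(score, brute)

    def test_seed_determinism(self):
        X, y = _toy_data(seed=6)
        m1 = bagging_train(X, y, n_members=10, seed=7)
        m2 = bagging_train(X, y, n_members=10, seed=7)
        assert np.array_equal(bagging_predict(m1, X)[1], bagging_predict(m2, X)[1])

    def test_tie_breaks_toward_paf(self):
        X, y = _toy_data(seed=8)
        model = bagging_train(X, y, n_members=2, seed=9)
        # force a tie artificially: one member voting each way
        labels, score = bagging_predict(model, X)
        ties = score == 0.5
        if np.any(ties):
            assert np.all(labels[ties] == "PAF")


class TestAdaBoost:
    def test_weight_update_hand_example(self):
        # 4 samples, uniform weights; member classifies 3 correctly:
        # eps = 0.25, beta = 1/3; weights (1/4 * 1/3 thrice, 1/4 once),
        # renormalised -> (1/6, 1/6, 1/6, 1/2)
        w = np.full(4, 0.25)
        correct = np.array([True, True, True, False])
        new_w, beta = _update_weights(w, correct, 0.25)
        assert beta == pytest.approx(1 / 3)
        assert np.allclose(new_w, [1 / 6, 1 / 6, 1 / 6, 1 / 2])
        assert new_w.sum() == pytest.approx(1.0)

    def test_round_invariants_on_training_history(self):
        X, y = _toy_data(n=40, seed=10, separation=1.0)
        model = adaboost_train(X, y, n_members=10, seed=11)
        assert np.allclose(model.diagnostics["weight_sums"], 1.0)
        assert np.all(model.diagnostics["member_weighted_accuracy"] > 0.5)
        assert np.all(model.member_weights > 0)
        assert np.all(np.isfinite(model.member_weights))

    def test_correct_samples_lose_relative_weight(self):
        # replay one training round by hand with the recorded eps
        w = np.full(6, 1 / 6)
        correct = np.array([True, False, True, True, False, True])
        new_w, _ = _update_weights(w, correct, 1 / 3)
        assert new_w[correct].max() < new_w[~correct].min()

    def test_equal_member_weights_reduce_to_majority_vote(self):
        X, y = _toy_data(seed=12)
        model = adaboost_train(X, y, n_members=9, seed=13)
        model.member_weights = np.ones(9)
        _, score = adaboost_predict(model, X)
        brute = np.mean([m.predict(X) == "PAF" for m in model.members], axis=0)
        assert np.allclose(score, brute)

    def test_weighted_vote_matches_brute_force(self):
        X, y = _toy_data(seed=14)
        model = adaboost_train(X, y, n_members=7, seed=15)
        _, score = adaboost_predict(model, X)
        votes = np.stack([m.predict(X) == "PAF" for m in model.members])
        brute = (model.member_weights[:, None] * votes).sum(0) / model.member_weights.sum()
        assert np.allclose(score, brute)

    def test_perfect_member_weight_capped(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0], [0.5], [10.5]])
        y = np.array(["normal", "normal", "PAF", "PAF", "normal", "PAF"])
        model = adaboost_train(X, y, n_members=3, seed=16,
                               spec=BaseLearnerSpec(complexity_parameter=0.01))
        assert np.all(np.isfinite(model.member_weights))


class TestStacking:
    def test_meta_features_one_column_per_layer1_model(self):
        X, y = _toy_data(n=40, seed=17)
        model = stacking_train(X, y, n_members=10, seed=18)
        assert model.diagnostics["meta_X"].shape == (40, 2)
        assert model.layer1_methods == ("bagging", "adaboost")

    def test_perfectly_informative_layer1_gives_perfect_training_accuracy(self):
        X, y = _toy_data(n=40, seed=19, separation=6.0)
        model = stacking_train(X, y, n_members=10, seed=20)
        labels, _ = stacking_predict(model, X)
        assert np.mean(labels == y) == 1.0

    def test_prediction_composes_layer1_through_logistic(self):
        from pafscreen.ensemble import _LAYER1_PREDICTORS

        X, y = _toy_data(n=40, seed=21)
        model = stacking_train(X, y, n_members=8, seed=22)
        meta_X = np.column_stack(
            [_LAYER1_PREDICTORS[m](mod, X)[1]
             for m, mod in zip(model.layer1_methods, model.members)]
        )
        z = model.meta_model.decision_function(meta_X)
        manual = 1.0 / (1.0 + np.exp(-z))
        classes = list(model.meta_model.classes_)
        p = manual if classes.index("PAF") == 1 else 1 - manual
        _, score = stacking_predict(model, X)
        assert np.allclose(score, p, atol=1e-12)

    def test_needs_two_layer1_models(self):
        X, y = _toy_data(seed=23)
        with pytest.raises(ConfigurationError):
            stacking_train(X, y, layer1_methods=("bagging",), seed=24)

    def test_seed_determinism(self):
        X, y = _toy_data(seed=25)
        s1 = stacking_predict(stacking_train(X, y, n_members=6, seed=26), X)[1]
        s2 = stacking_predict(stacking_train(X, y, n_members=6, seed=26), X)[1]
        assert np.array_equal(s1, s2)
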