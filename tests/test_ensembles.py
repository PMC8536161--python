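"""Contracts of the three deep-ensemble meta-algorithms."""

import numpy as np
import pytest

from deepens import (
    CLUSpec,
    ColumnMeanMeta,
    DALModel,
    DeSGELModel,
    build_clu,
    build_metadata,
    evaluate_predictions,
    fit_dal,
    fit_desgel,
    fit_gdlb,
    predict_dal,
    predict_desgel,
    predict_gdlb,
    train_clu,
)
from tests.conftest import scaled_fold


@pytest.fixture(scope="module")
def planted_fold():
    from deepens.synthetic import StatisticalGenSpec, gen_statistical

    table = gen_statistical(
        StatisticalGenSpec(n_samples=500, n_features=10, n_informative=4, effect_size=3.0, missing_rate=0.0, seed=11)
    )
    return scaled_fold(table, seed=11)


@pytest.fixture(scope="module")
def prob_spec():
    return CLUSpec(kind="mlp", layer_sizes=(16, 8, 1), epochs=30, seed=5, initial_lr=0.01)


@pytest.fixture(scope="module")
def reg_spec(prob_spec):
    return prob_spec.replace(output_mode="regression", loss="mean_squared_error", optimizer="sgd", initial_lr=0.01)


class _ExactFitOracle:
    """Regression oracle that memorises its training targets row-by-row."""

    def __init__(self, X, target):
        self.table = {row.tobytes(): t for row, t in zip(X, target)}

    def predict(self, X):
        return np.array([self.table[row.tobytes()] for row in np.asarray(X, dtype=float)])


class _ConstantFitOracle:
    """Least-squares-constant booster: predicts mean(target) everywhere."""

    def __init__(self, c):
        self.c = c

    def predict(self, X):
        return np.full(len(X), self.c)


class TestDAL:
    def test_mean_equals_explicit_loop_oracle_bitwise(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        model = fit_dal(train, val, prob_spec, n_members=4, seed=1)
        scores = predict_dal(model, test[0]).scores
        oracle = np.zeros(len(test[0]))
        for m in model.members:
            oracle = oracle + m.predict_proba(test[0])
        oracle = oracle / len(model.members)
        np.testing.assert_array_equal(scores, oracle)

    def test_hand_mean(self):
        class Fixed:
            def __init__(self, v):
                self.v = v
                self.spec = CLUSpec(kind="mlp", layer_sizes=(1,))

            def predict_proba(self, X):
                return np.full(len(X), self.v)

        model = DALModel(members=[Fixed(0.2), Fixed(0.4), Fixed(0.9)], subset_assignments=[np.arange(1)] * 3)
        assert predict_dal(model, np.zeros((1, 2))).scores[0] == pytest.approx(0.5)

    def test_single_member_full_subset_equals_single_clu(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        model = fit_dal(train, val, prob_spec, n_members=1, seed=9, subset_mode="disjoint")
        single = build_clu(prob_spec.replace(seed=9))
        single, _ = train_clu(single, train, val)
        np.testing.assert_array_equal(predict_dal(model, test[0]).scores, single.predict_proba(test[0]))

    def test_determinism_same_seed(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        a = fit_dal(train, val, prob_spec, n_members=3, seed=2)
        b = fit_dal(train, val, prob_spec, n_members=3, seed=2)
        np.testing.assert_array_equal(predict_dal(a, test[0]).scores, predict_dal(b, test[0]).scores)

    def test_planted_signal_accuracy(self, planted_fold, prob_spec):
        train, val, (X_test, y_test) = planted_fold
        model = fit_dal(train, val, prob_spec, n_members=5, seed=3)
        report = evaluate_predictions(y_test, predict_dal(model, X_test).scores)
        assert report.accuracy >= 0.95

    def test_mode_tie_breaks_positive(self):
        class Fixed:
            def __init__(self, v):
                self.v = v
                self.spec = CLUSpec(kind="mlp", layer_sizes=(1,))

            def predict_proba(self, X):
                return np.full(len(X), self.v)

        model = DALModel(
            members=[Fixed(0.9), Fixed(0.1)], subset_assignments=[np.arange(1)] * 2, aggregator="mode"
        )
        assert predict_dal(model, np.zeros((1, 2))).classes[0] == 1

    def test_variance_reduction_over_refits(self, planted_fold):
        """Ensemble score variance at a fixed point <= mean member variance."""
        train, val, test = planted_fold
        spec = CLUSpec(kind="mlp", layer_sizes=(8, 1), epochs=10, seed=0, initial_lr=0.01)
        point = test[0][:1]
        ens_scores, member_scores = [], []
        for r in range(20):
            model = fit_dal(train, val, spec, n_members=4, seed=100 + r)
            ens_scores.append(predict_dal(model, point).scores[0])
            member_scores.append([m.predict_proba(point)[0] for m in model.members])
        ens_var = np.var(ens_scores)
        member_var = np.var(np.array(member_scores).ravel())
        assert ens_var <= member_var * 1.05


class TestGDLB:
    def test_base_prediction_is_label_mean(self, reg_spec):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.arange(8.0).reshape(4, 2)
        model = fit_gdlb(
            (X, y), (X, y), reg_spec, n_boosters=1, lr_policy=0.5, seed=0,
            booster_fitter=lambda i, Xt, t, v: _ConstantFitOracle(0.0),
        )
        assert model.p_base == 0.5
        np.testing.assert_allclose(predict_gdlb(model, X).scores, 0.5)

    def test_exact_oracle_lambda_one_zero_residual(self, reg_spec):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20).astype(float)
        model = fit_gdlb(
            (X, y), (X, y), reg_spec, n_boosters=1, lr_policy=1.0, seed=0,
            booster_fitter=lambda i, Xt, t, v: _ExactFitOracle(Xt, t),
        )
        assert model.staged_train_mse[-1] == pytest.approx(0.0, abs=1e-24)
        np.testing.assert_allclose(predict_gdlb(model, X).scores, y, atol=1e-12)

    def test_constant_oracle_mse_nonincreasing(self, reg_spec):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, 50).astype(float)
        model = fit_gdlb(
            (X, y), (X, y), reg_spec, n_boosters=10, lr_policy=0.5, seed=0,
            booster_fitter=lambda i, Xt, t, v: _ConstantFitOracle(float(t.mean())),
        )
        staged = model.staged_train_mse
        assert all(a >= b - 1e-12 for a, b in zip(staged, staged[1:]))

    def test_hand_raw_score(self, reg_spec):
        y = np.array([0.0, 1.0])
        X = np.zeros((2, 2))
        model = fit_gdlb(
            (X, y), (X, y), reg_spec, n_boosters=1, lr_policy=0.5, seed=0,
            booster_fitter=lambda i, Xt, t, v: _ConstantFitOracle(0.4),
        )
        # P_base=0.5, booster output 0.4, lambda=0.5 -> raw 0.7
        np.testing.assert_allclose(predict_gdlb(model, X).scores, 0.7)

    def test_zero_output_boosters_leave_base(self, reg_spec):
        y = np.array([0.0, 1.0, 1.0])
        X = np.zeros((3, 2))
        model = fit_gdlb(
            (X, y), (X, y), reg_spec, n_boosters=5, lr_policy=0.9, seed=0,
            booster_fitter=lambda i, Xt, t, v: _ConstantFitOracle(0.0),
        )
        np.testing.assert_allclose(predict_gdlb(model, X).scores, model.p_base)

    def test_uniform_lambda_policy_in_unit_interval(self, planted_fold, reg_spec):
        train, val, _ = planted_fold
        model = fit_gdlb(train, val, reg_spec.replace(epochs=5), n_boosters=3, lr_policy="uniform", seed=4)
        assert all(0 < lam < 1 for lam in model.learning_rates)

    def test_planted_signal_accuracy(self, planted_fold, reg_spec):
        """Mean accuracy over re-seeded fits (the random λ draws vary per run)."""
        train, val, (X_test, y_test) = planted_fold
        accs = []
        for r in range(3):
            model = fit_gdlb(train, val, reg_spec, n_boosters=5, lr_policy="uniform", seed=3 + r)
            accs.append(evaluate_predictions(y_test, predict_gdlb(model, X_test).scores).accuracy)
        assert np.mean(accs) >= 0.9

    def test_probability_spec_rejected(self, prob_spec):
        with pytest.raises(ValueError):
            fit_gdlb((np.zeros((4, 2)), np.zeros(4)), (np.zeros((2, 2)), np.zeros(2)), prob_spec, n_boosters=1)

    def test_zero_boosters_rejected(self, reg_spec):
        with pytest.raises(ValueError):
            fit_gdlb((np.zeros((4, 2)), np.zeros(4)), (np.zeros((2, 2)), np.zeros(2)), reg_spec, n_boosters=0)


class TestDeSGEL:
    def test_metadata_columns_match_member_outputs_bitwise(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        model = fit_desgel(train, val, prob_spec, n_members=3, seed=6)
        M = build_metadata(model.level0, test[0])
        assert M.shape == (len(test[0]), 3)
        for j, member in enumerate(model.level0):
            np.testing.assert_array_equal(M[:, j], member.predict_proba(test[0]))

    def test_duplicated_input_row_duplicates_metadata_row(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        model = fit_desgel(train, val, prob_spec, n_members=2, seed=6)
        X = np.vstack([test[0][:1], test[0][:1]])
        M = build_metadata(model.level0, X)
        np.testing.assert_array_equal(M[0], M[1])

    def test_column_mean_meta_reduces_to_dal(self, planted_fold, prob_spec):
        """Stacking with an averaging meta-learner IS bagging's aggregation."""
        train, val, test = planted_fold
        stacked = fit_desgel(train, val, prob_spec, n_members=3, level1_spec="mean", seed=8)
        bagged = DALModel(members=stacked.level0, subset_assignments=[np.arange(len(train[0]))] * 3)
        np.testing.assert_array_equal(
            predict_desgel(stacked, test[0]).scores, predict_dal(bagged, test[0]).scores
        )

    def test_single_member_monotone_meta_preserves_ranking(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        model = fit_desgel(train, val, prob_spec, n_members=1, level1_spec="logistic", seed=2)
        member_scores = model.level0[0].predict_proba(test[0])
        stack_scores = predict_desgel(model, test[0]).scores
        np.testing.assert_array_equal(np.argsort(member_scores, kind="stable"), np.argsort(stack_scores, kind="stable"))

    def test_scores_in_unit_interval(self, planted_fold, prob_spec, rng):
        train, val, _ = planted_fold
        model = fit_desgel(train, val, prob_spec, n_members=2, seed=1)
        scores = predict_desgel(model, rng.normal(size=(100, train[0].shape[1]))).scores
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_planted_signal_accuracy(self, planted_fold, prob_spec):
        train, val, (X_test, y_test) = planted_fold
        model = fit_desgel(train, val, prob_spec, n_members=5, seed=3)
        assert evaluate_predictions(y_test, predict_desgel(model, X_test).scores).accuracy >= 0.95

    def test_stacked_not_much_worse_than_best_member(self, planted_fold, prob_spec):
        train, (X_val, y_val), _ = planted_fold
        model = fit_desgel(train, (X_val, y_val), prob_spec, n_members=3, seed=4)
        member_acc = [np.mean((m.predict_proba(X_val) >= 0.5) == y_val) for m in model.level0]
        stacked_acc = np.mean(predict_desgel(model, X_val).classes == y_val)
        assert stacked_acc >= max(member_acc) - 0.02

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            build_metadata([], np.zeros((3, 2)))

    def test_determinism_same_seed(self, planted_fold, prob_spec):
        train, val, test = planted_fold
        a = fit_desgel(train, val, prob_spec, n_members=2, seed=5)
        b = fit_desgel(train, val, prob_spec, n_members=2, seed=5)
        np.testing.assert_array_equal(predict_desgel(a, test[0]).scores, predict_desgel(b, test[0]).scores)


class TestColumnMeanMeta:
    def test_row_means(self):
        M = np.array([[0.2, 0.4], [1.0, 0.0]])
        np.testing.assert_allclose(ColumnMeanMeta().fit(M, None).predict_proba_scores(M), [0.3, 0.5])
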