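import numpy as np
import pytest

from sparselink import (
    Family,
    HyperparameterGrid,
    Mode,
    Problem,
    ProblemSet,
    SolverConfig,
    SparselinkModel,
    coefficients,
    fit,
    predict,
    select_hyperparameters,
)

from conftest import make_gaussian_set

SMALL_GRID = HyperparameterGrid(delta_candidates=(0.0, 0.5, 1.0), n_lambda=25)


@pytest.fixture(scope="module")
def fitted(rng_module):
    ps = make_gaussian_set(rng_module, q=2, p=10, n=40)
    return ps, fit(ps, SMALL_GRID, n_folds=5, seed=11)


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(999)


class TestSelectHyperparameters:
    def test_single_entry(self):
        assert select_hyperparameters({(0.3, 0.2, 0.4): 1.0}) == (0.3, 0.2, 0.4)

    def test_tie_prefers_no_transfer_then_no_adaptation(self):
        table = {(0.3, 0.2, 0.2): 1.0, (0.3, 0.0, 0.0): 1.0}
        assert select_hyperparameters(table) == (0.3, 0.0, 0.0)

    def test_tie_prefers_larger_lambda(self):
        table = {(0.1, 0.0, 0.0): 2.0, (0.5, 0.0, 0.0): 2.0}
        assert select_hyperparameters(table) == (0.5, 0.0, 0.0)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            select_hyperparameters({})


class TestFit:
    def test_null_targets_give_null_model(self, rng):
        n, p = 30, 8
        X = rng.standard_normal((n, p))
        problems = [Problem(X, np.zeros(n), id="null")]
        ps = ProblemSet(Mode.multi_task, problems, Family.gaussian)
        model = fit(ps, SMALL_GRID, n_folds=5, seed=0)
        assert np.all(model.fits[0].slopes == 0)
        assert model.fits[0].intercept == 0.0

    def test_deterministic_given_seed(self, rng_module):
        ps = make_gaussian_set(rng_module, q=2, p=8, n=30)
        m1 = fit(ps, SMALL_GRID, n_folds=5, seed=3)
        m2 = fit(ps, SMALL_GRID, n_folds=5, seed=3)
        for f1, f2 in zip(m1.fits, m2.fits):
            assert f1.lambda2 == f2.lambda2
            assert (f1.delta_int, f1.delta_ext) == (f2.delta_int, f2.delta_ext)
            np.testing.assert_array_equal(f1.gamma, f2.gamma)

    def test_sign_exclusivity_of_stored_gamma(self, fitted):
        _, model = fitted
        p = model.p
        for f in model.fits:
            assert np.minimum(f.gamma[:p], f.gamma[p:]).max() <= 1e-8

    def test_stage2_support_within_finite_factors(self, fitted):
        _, model = fitted
        for f in model.fits:
            assert np.count_nonzero(f.slopes) <= model.p

    def test_hyperparameters_come_from_grid(self, fitted):
        _, model = fitted
        for f in model.fits:
            assert f.delta_int in SMALL_GRID.delta_candidates
            assert f.delta_ext in SMALL_GRID.delta_candidates
            assert f.lambda1 > 0 and f.lambda2 > 0


class TestPredictAndCoefficients:
    def test_training_predictions_match_fitted_values(self, fitted):
        ps, model = fitted
        for k, pr in enumerate(ps.problems):
            np.testing.assert_allclose(
                predict(model, pr.features, k), model.fits[k].fitted_values
            )

    def test_zero_matrix_predicts_intercept(self, fitted):
        _, model = fitted
        out = predict(model, np.zeros((4, model.p)), 0, "response")
        np.testing.assert_allclose(out, model.fits[0].intercept)

    def test_wrong_column_count_raises(self, fitted):
        _, model = fitted
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, model.p + 2)), 0)

    def test_dataframe_alignment_by_name(self, fitted):
        import pandas as pd

        ps, model = fitted
        X = pd.DataFrame(ps.problems[0].features, columns=model.feature_names)
        shuffled = X[list(reversed(model.feature_names))]
        np.testing.assert_allclose(
            predict(model, shuffled, 0), predict(model, X, 0)
        )

    def test_coefficient_matrix_structure(self, fitted):
        _, model = fitted
        cm = coefficients(model)
        assert cm.slopes.shape == (model.p, model.q)
        for k, f in enumerate(model.fits):
            assert cm.intercepts[k] == f.intercept
            np.testing.assert_array_equal(cm.slopes[:, k], f.slopes)


class TestSerialisation:
    def test_round_trip_reproduces_predictions(self, fitted, tmp_path):
        ps, model = fitted
        path = str(tmp_path / "model.json")
        model.to_json(path)
        back = SparselinkModel.from_json(path)
        for k, pr in enumerate(ps.problems):
            np.testing.assert_array_equal(
                predict(model, pr.features, k), predict(back, pr.features, k)
            )
        assert back.grid.delta_candidates == model.grid.delta_candidates
        for a, b in zip(back.folds.assignments, model.folds.assignments):
            np.testing.assert_array_equal(a, b)


class TestReductions:
    def test_transfer_delta_ext_zero_is_local(self, rng_module):
        """With the external exponent pinned at zero, a problem's fit is a
        function of its own dataset only (transfer mode)."""
        grid = HyperparameterGrid(
            delta_candidates=(0.0, 0.5, 1.0),
            n_lambda=20,
            delta_ext_candidates=(0.0,),
        )
        ps_a = make_gaussian_set(rng_module, mode=Mode.transfer, q=3, p=8, n=30)
        # same first problem, the others replaced by fresh noise
        noise_rng = np.random.default_rng(5)
        problems_b = [ps_a.problems[0]] + [
            Problem(
                noise_rng.standard_normal((30, 8)),
                noise_rng.standard_normal(30),
                id=pr.id,
            )
            for pr in ps_a.problems[1:]
        ]
        ps_b = ProblemSet(Mode.transfer, problems_b, Family.gaussian)
        m_a = fit(ps_a, grid, n_folds=5, seed=21)
        m_b = fit(ps_b, grid, n_folds=5, seed=21)
        np.testing.assert_array_equal(m_a.fits[0].gamma, m_b.fits[0].gamma)
        assert m_a.fits[0].lambda2 == m_b.fits[0].lambda2
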