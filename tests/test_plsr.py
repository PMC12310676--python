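"""NIPALS PLSR: oracle equivalences, invariants, combination evaluation."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from canopy2sat import ablation_table, evaluate_combination, fit_plsr, predict_plsr
from canopy2sat.metrics import r_squared
from canopy2sat.sensors import SimulatedBandTable


def random_problem(rng, n=20, p=5, noise=0.1):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def ols_predictions(X, y):
    """Normal-equations least squares with intercept — the independent oracle."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef


class TestFitPLSR:
    def test_full_components_equal_ols(self, rng):
        for _ in range(50):
            n, p = int(rng.integers(8, 25)), int(rng.integers(2, 7))
            X, y = random_problem(rng, n=n, p=p)
            model = fit_plsr(X, y, n_components=p)
            assert np.allclose(predict_plsr(model, X), ols_predictions(X, y), atol=1e-8)

    def test_single_predictor_equals_simple_regression(self, rng):
        x = rng.normal(size=15)
        y = 2.5 * x + 1.0 + 0.2 * rng.normal(size=15)
        model = fit_plsr(x[:, None], y, 1)
        slope, intercept = np.polyfit(x, y, 1)
        assert np.allclose(predict_plsr(model, x[:, None]), slope * x + intercept,
                           atol=1e-10)

    def test_training_r2_nondecreasing_in_components(self, rng):
        X, y = random_problem(rng, n=40, p=6, noise=0.5)
        r2s = []
        for k in range(1, 7):
            model = fit_plsr(X, y, k)
            r2s.append(r_squared(y, predict_plsr(model, X)))
        assert np.all(np.diff(r2s) >= -1e-10)

    def test_score_orthogonality(self, rng):
        for _ in range(10):
            X, y = random_problem(rng, n=10, p=8, noise=0.3)
            T = fit_plsr(X, y, 5).x_scores
            gram = T.T @ T
            off = gram - np.diag(np.diag(gram))
            assert np.max(np.abs(off)) <= 1e-8 * np.max(np.abs(gram))

    def test_coefficient_path_equals_deflation_recursion(self, rng):
        """ŷ through back-transformed coefficients equals y_mean + T q."""
        X, y = random_problem(rng, n=30, p=5, noise=0.4)
        model = fit_plsr(X, y, 3)
        via_coef = predict_plsr(model, X)
        via_scores = model.y_mean + model.x_scores @ model.y_loadings
        assert np.allclose(via_coef, via_scores, atol=1e-10)

    def test_matches_sklearn_pls(self, rng):
        """Cross-check against an independent PLS implementation."""
        X, y = random_problem(rng, n=40, p=6, noise=0.3)
        for k in (1, 2, 4):
            ours = predict_plsr(fit_plsr(X, y, k), X)
            theirs = PLSRegression(n_components=k, scale=True).fit(X, y).predict(X).ravel()
            assert np.allclose(ours, theirs, atol=1e-8)

    def test_zero_variance_predictor_named(self, rng):
        X, y = random_problem(rng, n=12, p=3)
        X[:, 1] = 0.7
        with pytest.raises(ValueError, match="Green"):
            fit_plsr(X, y, 2, predictor_names=["Red", "Green", "Blue"])

    def test_component_count_validation(self, rng):
        X, y = random_problem(rng, n=12, p=3)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 4)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 0)


class TestPredictPLSR:
    def test_mean_row_predicts_y_mean(self, rng):
        X, y = random_problem(rng, n=25, p=4)
        model = fit_plsr(X, y, 2)
        assert predict_plsr(model, X.mean(axis=0))[0] == pytest.approx(
            model.y_mean, abs=1e-10
        )

    def test_column_rescaling_invariance(self, rng):
        """Autoscaling makes predictions invariant to predictor units."""
        X, y = random_problem(rng, n=30, p=4)
        base = predict_plsr(fit_plsr(X, y, 3), X)
        X2 = X.copy()
        X2[:, 2] *= 1000.0
        rescaled = predict_plsr(fit_plsr(X2, y, 3), X2)
        assert np.allclose(base, rescaled, atol=1e-8)

    def test_dimension_mismatch(self, rng):
        X, y = random_problem(rng, n=12, p=4)
        model = fit_plsr(X, y, 2)
        with pytest.raises(ValueError):
            predict_plsr(model, X[:, :3])


def toy_table(rng, n=200, names=("A", "B", "C", "D")):
    values = rng.uniform(0.1, 0.9, (n, len(names)))
    return SimulatedBandTable(
        sensor="toy", stage="NGS", sample_ids=[f"s{i}" for i in range(n)],
        band_names=list(names), values=values, nitrogen=rng.normal(3.0, 0.3, n),
    )


class TestEvaluateCombination:
    def test_self_consistency_r2_one(self, rng):
        """Refitting on a previous full-component fit's values gives R² = 1."""
        table = toy_table(rng, n=50)
        model = fit_plsr(table.values, table.nitrogen, 4)
        fitted = predict_plsr(model, table.values)
        rep = evaluate_combination(table, table.band_names, y=fitted, n_components=4)
        assert rep.r2_train == pytest.approx(1.0, abs=1e-9)

    def test_null_r2_is_small(self, rng):
        table = toy_table(rng, n=200)  # nitrogen independent of the bands
        rep = evaluate_combination(table, table.band_names)
        assert rep.r2_train < 0.1

    def test_unknown_band_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate_combination(toy_table(rng), ["A", "Z"])

    def test_red_edge_bands_add_accuracy_on_synthetic_data(self, sentinel2_table):
        with_re = evaluate_combination(
            sentinel2_table, ["Red", "Blue", "RE1", "RE2", "RE3", "NIR1"]
        )
        without_re = evaluate_combination(sentinel2_table, ["Red", "Blue", "NIR1"])
        assert with_re.r2_train >= without_re.r2_train


class TestAblationTable:
    def test_empty_removable_gives_single_base_report(self, rng):
        reports = ablation_table(toy_table(rng, n=40), ["A", "B"], [])
        assert len(reports) == 1 and reports[0].delta_r2 is None

    def test_duplicated_band_removal_changes_nothing(self, rng):
        table = toy_table(rng, n=40)
        values = np.column_stack([table.values, table.values[:, 0]])
        dup = SimulatedBandTable(
            sensor="toy", stage="NGS", sample_ids=table.sample_ids,
            band_names=["A", "B", "C", "D", "A2"], values=values,
            nitrogen=table.nitrogen,
        )
        # at rank-spanning components both fits equal OLS on the same span,
        # so dropping the redundant copy cannot change the fit
        reports = ablation_table(dup, ["A", "B", "C", "D", "A2"], ["A2"],
                                 n_components=4)
        assert reports[1].delta_r2 == pytest.approx(0.0, abs=1e-8)

    def test_removing_planted_signal_band_hurts_most(self, rng):
        """The band carrying the only real signal has the largest ΔR²."""
        n = 150
        values = rng.uniform(0.2, 0.8, (n, 4))
        nitrogen = 3.0 + 2.0 * (values[:, 2] - 0.5) + 0.05 * rng.normal(size=n)
        table = SimulatedBandTable(
            sensor="toy", stage="NGS", sample_ids=[f"s{i}" for i in range(n)],
            band_names=["A", "B", "S", "D"], values=values, nitrogen=nitrogen,
        )
        reports = ablation_table(table, ["A", "B", "S", "D"], ["A", "B", "S", "D"])
        deltas = {r.band_combination: r.delta_r2 for r in reports[1:]}
        worst = max(deltas, key=deltas.get)
        assert "S" not in worst  # the removal that drops S hurts most
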