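import numpy as np
import pytest

import flowstack as fs
from flowstack.models import PREDICTION_FLOOR


def _random_predictions(seed, n, scale=50.0):
    """Five synthetic, mutually independent positive 'base predictions'."""
    rng = np.random.default_rng(seed)
    ids = tuple(f"r{i}" for i in range(n))
    preds = []
    for _ in range(5):
        v = scale * np.exp(rng.normal(0.0, 0.6, size=(n, n)))
        np.fill_diagonal(v, 0.0)
        preds.append(fs.ODMatrix(values=v, ids=ids))
    return ids, preds


def _base_model_predictions(locs, geom):
    params = {
        "gravity": fs.DEFAULT_GRAVITY_PARAMS,
        "gravity_distance": fs.GravityDistanceParams(
            delta=150.0,
            short=fs.GravityParams(theta=0.5, alpha=0.8, beta=0.6, gamma=1.6),
            long=fs.GravityParams(theta=0.2, alpha=0.8, beta=0.6, gamma=1.3),
        ),
        "radiation": fs.RadiationParams(theta=30.0),
        "radiation_selection": fs.RadiationSelectionParams(theta=25.0, lam=0.5),
        "intervening_opportunities": fs.DEFAULT_IO_PARAMS,
    }
    return [fs.predict_matrix(m, params[m], locs, geom) for m in fs.MODEL_IDS]


class TestBuildDesign:
    def test_row_count_is_offdiagonal_cells(self):
        _, preds = _random_predictions(0, 3)
        X, cells = fs.build_design(preds)
        assert X.shape == (6, 5)
        assert len(cells) == 6

    def test_zero_prediction_clamped_to_log_floor(self):
        ids, preds = _random_predictions(1, 3)
        v = preds[2].values.copy()
        v[0, 1] = 0.0
        preds[2] = fs.ODMatrix(values=v, ids=ids)
        X, cells = fs.build_design(preds)
        row = np.flatnonzero((cells == [0, 1]).all(axis=1))[0]
        assert X[row, 2] == pytest.approx(np.log(PREDICTION_FLOOR))

    def test_collinear_columns_are_preserved(self):
        ids, preds = _random_predictions(2, 4)
        preds[3] = fs.ODMatrix(values=preds[2].values.copy(), ids=ids)
        X, _ = fs.build_design(preds)
        assert np.array_equal(X[:, 2], X[:, 3])

    def test_misaligned_predictions_rejected(self):
        _, preds = _random_predictions(3, 4)
        _, other = _random_predictions(3, 5)
        with pytest.raises(fs.InvalidInputError):
            fs.build_design(preds[:4] + [other[0]])


class TestFitEnsemble:
    def test_recovers_a_single_true_base_model(self):
        """When the observations equal one base prediction exactly, the GLM
        puts weight 1 on it, zero intercept, and fits with ~zero deviance."""
        ids, preds = _random_predictions(4, 10)
        observed = fs.ODMatrix(values=preds[0].values.copy(), ids=ids)
        ens = fs.fit_ensemble(observed, preds)
        assert ens.converged
        assert ens.training_deviance == pytest.approx(0.0, abs=1e-6)
        assert ens.weights["gravity"] == pytest.approx(1.0, abs=1e-4)
        assert ens.intercept == pytest.approx(0.0, abs=1e-3)
        for mid in fs.MODEL_IDS[1:]:
            assert ens.weights[mid] == pytest.approx(0.0, abs=1e-4)

    def test_constant_design_reduces_to_intercept_model(self):
        """With all base predictions constant, the GLM fits the observed
        mean: b0 + sum(b_a) log(c) == log(mean(y))."""
        n, c = 8, 20.0
        ids = tuple(f"r{i}" for i in range(n))
        v = np.full((n, n), c)
        np.fill_diagonal(v, 0.0)
        preds = [fs.ODMatrix(values=v.copy(), ids=ids) for _ in range(5)]
        rng = np.random.default_rng(8)
        y = rng.poisson(c, size=(n, n)).astype(float)
        np.fill_diagonal(y, 0.0)
        observed = fs.ODMatrix(values=y, ids=ids)
        ens = fs.fit_ensemble(observed, preds)
        off = ~np.eye(n, dtype=bool)
        eta = ens.intercept + sum(ens.weights.values()) * np.log(c)
        assert eta == pytest.approx(np.log(y[off].mean()), abs=1e-6)

    def test_recovers_mixture_coefficients(self):
        """Generating log-linear weights are recovered from large counts."""
        ids, preds = _random_predictions(5, 40, scale=200.0)
        X, cells = fs.build_design(preds)
        mu = np.exp(0.3 + 0.6 * X[:, 0] + 0.4 * X[:, 4])
        rng = np.random.default_rng(6)
        y = np.zeros((40, 40))
        y[cells[:, 0], cells[:, 1]] = rng.poisson(mu)
        observed = fs.ODMatrix(values=y, ids=ids)
        ens = fs.fit_ensemble(observed, preds)
        truth = {"gravity": 0.6, "intervening_opportunities": 0.4,
                 "gravity_distance": 0.0, "radiation": 0.0, "radiation_selection": 0.0}
        assert ens.intercept == pytest.approx(0.3, abs=0.05)
        for mid, w in truth.items():
            assert ens.weights[mid] == pytest.approx(w, abs=0.05)

    def test_agrees_with_statsmodels_glm(self):
        """Independent cross-check: statsmodels' Poisson GLM reaches the
        same coefficients and deviance on a well-conditioned design."""
        import statsmodels.api as sm

        ids, preds = _random_predictions(7, 15)
        X, cells = fs.build_design(preds)
        rng = np.random.default_rng(7)
        mu = np.exp(0.2 + 0.5 * X[:, 1] + 0.3 * X[:, 3])
        y_vec = rng.poisson(mu).astype(float)
        y = np.zeros((15, 15))
        y[cells[:, 0], cells[:, 1]] = y_vec
        observed = fs.ODMatrix(values=y, ids=ids)
        ens = fs.fit_ensemble(observed, preds)
        ref = sm.GLM(y_vec, sm.add_constant(X), family=sm.families.Poisson()).fit()
        assert ens.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert ens.training_deviance == pytest.approx(ref.deviance, rel=1e-8)

    def test_training_deviance_beats_every_pure_weighting(self, mixture_data):
        """The GLM optimum cannot be worse than any single base model or
        the equal-weight average (training data, genuine model fixtures)."""
        locs, geom, od = mixture_data
        preds = _base_model_predictions(locs, geom)
        ens = fs.fit_ensemble(od, preds)
        off = ~np.eye(locs.n, dtype=bool)
        y = od.values[off]
        slack = 1e-8 * (1 + ens.training_deviance)
        for p in preds:
            assert ens.training_deviance <= fs.poisson_deviance(y, p.values[off]) + slack
        mean_pred = np.mean([p.values for p in preds], axis=0)
        assert ens.training_deviance <= fs.poisson_deviance(y, mean_pred[off]) + slack

    def test_training_mu_round_trip(self, mixture_data):
        """predict_ensemble reproduces the mu vector the fit scored."""
        locs, geom, od = mixture_data
        preds = _base_model_predictions(locs, geom)
        ens = fs.fit_ensemble(od, preds)
        mu = fs.predict_ensemble(ens, preds)
        off = ~np.eye(locs.n, dtype=bool)
        dev = fs.poisson_deviance(od.values[off], mu.values[off])
        assert dev == pytest.approx(ens.training_deviance, rel=1e-8)


class TestPredictEnsemble:
    def test_identity_weighting_returns_base_model(self):
        ids, preds = _random_predictions(9, 8)
        ens = fs.StackedEnsemble(
            intercept=0.0,
            weights={m: (1.0 if m == "gravity" else 0.0) for m in fs.MODEL_IDS},
            converged=True, training_deviance=0.0, n_iterations=0,
        )
        out = fs.predict_ensemble(ens, preds)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(out.values[off], preds[0].values[off])
        assert np.all(np.diag(out.values) == 0)

    def test_zero_weights_give_constant_surface(self):
        _, preds = _random_predictions(10, 6)
        ens = fs.StackedEnsemble(
            intercept=0.0, weights={m: 0.0 for m in fs.MODEL_IDS},
            converged=True, training_deviance=0.0, n_iterations=0,
        )
        out = fs.predict_ensemble(ens, preds)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(out.values[off], 1.0)

    def test_log_linearity_in_base_predictions(self):
        ids, preds = _random_predictions(11, 6)
        w = {m: 0.0 for m in fs.MODEL_IDS}
        w["gravity"] = 0.5
        ens = fs.StackedEnsemble(intercept=0.0, weights=w, converged=True,
                                 training_deviance=0.0, n_iterations=0)
        base = fs.predict_ensemble(ens, preds)
        doubled = [fs.ODMatrix(values=preds[0].values * 2, ids=ids)] + preds[1:]
        out = fs.predict_ensemble(ens, doubled)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(out.values[off], np.sqrt(2) * base.values[off])

    def test_overflow_capped_with_warning(self, caplog):
        ids, preds = _random_predictions(12, 4)
        w = {m: 0.0 for m in fs.MODEL_IDS}
        ens = fs.StackedEnsemble(intercept=800.0, weights=w, converged=True,
                                 training_deviance=0.0, n_iterations=0)
        with caplog.at_level("WARNING", logger="flowstack"):
            out = fs.predict_ensemble(ens, preds)
        assert np.all(np.isfinite(out.values))
        assert out.values.max() <= 1e15
        assert "capping" in caplog.text
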