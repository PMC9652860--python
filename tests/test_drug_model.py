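"""Final per-drug elastic net: optimality, prediction, evaluation."""

import numpy as np
import pytest

import edgeqnet as eq
from edgeqnet._enet import fit_enet, kkt_residual, standardize
from edgeqnet.errors import ConfigError, DegenerateInputError, MissingMoleculeError


def _matrix(rng, n, p, prefix="E"):
    return eq.EdgeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        edge_ids=[f"{prefix}{i}" for i in range(p)],
        strengths=rng.normal(size=(n, p)),
        states=np.array([1] * (n // 2) + [2] * (n - n // 2)),
    )


class TestFitDrugModel:
    def test_huge_lambda_fully_shrinks_to_intercept(self, rng, responses_for):
        m = _matrix(rng, 20, 4)
        resp = responses_for(m.sample_ids, np.full(20, 42.0))
        model = eq.fit_drug_model(m, resp, "drugA", alpha=0.5, lam=1e6)
        assert model.intercept == pytest.approx(42.0)
        assert np.array_equal(model.coefficients, np.zeros(4))

    def test_tiny_lambda_recovers_noiseless_coefficients(self, rng, responses_for):
        m = _matrix(rng, 30, 2)
        y = 2.0 * m.strengths[:, 0] - 3.0 * m.strengths[:, 1]
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=0.5, lam=1e-6)
        assert model.coefficients == pytest.approx([2.0, -3.0], abs=1e-3)

    def test_lambda_zero_matches_normal_equations(self, rng, responses_for):
        m = _matrix(rng, 30, 5)
        y = m.strengths @ rng.normal(size=5) + rng.normal(size=30)
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=0.3, lam=0.0)
        # closed-form OLS oracle with intercept
        A = np.hstack([np.ones((30, 1)), m.strengths])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)
        assert model.coefficients == pytest.approx(beta[1:], abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_kkt_conditions_hold(self, rng, responses_for, alpha):
        m = _matrix(rng, 30, 10)
        y = m.strengths[:, 0] - m.strengths[:, 5] + 0.5 * rng.normal(size=30)
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=alpha, lam=0.05)
        assert model.kkt_residual(m.strengths, y) < 1e-6

    def test_agrees_with_sklearn_elastic_net(self, rng, responses_for):
        """Independent cross-check against scikit-learn's coordinate descent."""
        from sklearn.linear_model import ElasticNet

        n, p = 40, 6
        Xs, _, _ = standardize(rng.normal(size=(n, p)))
        y = Xs @ rng.normal(size=p) + rng.normal(size=n)
        for alpha, lam in [(1.0, 0.05), (0.5, 0.1), (0.2, 0.02)]:
            intercept, coef, _, _ = fit_enet(Xs, y, l1_ratio=alpha, lam=lam)
            sk = ElasticNet(
                alpha=lam, l1_ratio=alpha, fit_intercept=True,
                tol=1e-12, max_iter=1_000_000,
            ).fit(Xs, y)
            assert coef == pytest.approx(sk.coef_, abs=1e-5)
            assert intercept == pytest.approx(sk.intercept_, abs=1e-5)

    def test_monotone_l1_shrinkage_along_path(self, rng):
        from edgeqnet._enet import lambda_grid, solve_path

        X, _, _ = standardize(rng.normal(size=(25, 8)))
        y = X @ rng.normal(size=8) + 0.2 * rng.normal(size=25)
        yc = y - y.mean()
        for alpha in (0.2, 1.0):
            lambdas = lambda_grid(X, yc, alpha, n_lambdas=50)
            coefs = solve_path(X, yc, lambdas, alpha)
            norms = np.abs(coefs).sum(axis=1)  # λ descending → norms must rise
            assert np.all(np.diff(norms) >= -1e-8)

    @pytest.mark.parametrize("alpha,lam", [(-0.1, 1.0), (1.5, 1.0), (0.5, -1.0)])
    def test_invalid_hyperparameters_rejected(self, rng, responses_for, alpha, lam):
        m = _matrix(rng, 10, 2)
        resp = responses_for(m.sample_ids, rng.normal(size=10))
        with pytest.raises(ConfigError):
            eq.fit_drug_model(m, resp, "drugA", alpha=alpha, lam=lam)


class TestPredict:
    @pytest.fixture()
    def fitted(self, rng, responses_for):
        m = _matrix(rng, 24, 3)
        y = 1.5 * m.strengths[:, 0] + 0.1 * rng.normal(size=24) + 50.0
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=0.5, lam=0.01)
        return model, m, y

    def test_zero_vector_predicts_intercept(self, fitted):
        model, _, _ = fitted
        assert eq.predict_tcgi(model, np.zeros(3)) == pytest.approx(model.intercept)

    def test_training_sample_interpolated_at_tiny_lambda(self, rng, responses_for):
        m = _matrix(rng, 25, 3)
        y = m.strengths @ np.array([2.0, -1.0, 0.5]) + 10.0
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=0.5, lam=1e-8)
        preds = eq.predict_cohort(model, m)
        assert preds == pytest.approx(y, abs=1e-3)

    def test_fully_shrunk_model_predicts_training_mean(self, rng, responses_for):
        m = _matrix(rng, 20, 3)
        y = rng.normal(30.0, 5.0, 20)
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=1.0, lam=1e5)
        for row in m.strengths[:4]:
            assert eq.predict_tcgi(model, row) == pytest.approx(y.mean())

    def test_mapping_input_and_missing_feature(self, fitted):
        model, m, _ = fitted
        vec = {eid: float(v) for eid, v in zip(m.edge_ids, m.strengths[0])}
        assert eq.predict_tcgi(model, vec) == pytest.approx(
            eq.predict_tcgi(model, m.strengths[0])
        )
        del vec[m.edge_ids[1]]
        with pytest.raises(MissingMoleculeError) as exc:
            eq.predict_tcgi(model, vec)
        assert m.edge_ids[1] in exc.value.missing

    def test_prediction_stable_across_save_load(self, fitted, tmp_path):
        model, m, _ = fitted
        before = eq.predict_cohort(model, m)
        eq.save_model(model, tmp_path / "m.json")
        again = eq.load_model(tmp_path / "m.json")
        assert np.array_equal(eq.predict_cohort(again, m), before)

    def test_clipping_bounds_predictions(self, rng, responses_for):
        m = _matrix(rng, 20, 2)
        y = 200.0 * m.strengths[:, 0]
        resp = responses_for(m.sample_ids, y)
        model = eq.fit_drug_model(m, resp, "drugA", alpha=0.5, lam=1e-6)
        preds = eq.predict_cohort(model, m, clip=True)
        assert preds.min() >= 0.0 and preds.max() <= 100.0


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        y = rng.normal(size=10)
        res = eq.evaluate(y, y)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-10
        assert res.cod == pytest.approx(1.0)

    def test_anticorrelated_predictions_have_unit_r_squared(self, rng):
        y = rng.normal(size=10)
        res = eq.evaluate(-y, y)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        """Direct-formula oracle for r, R², and the t-based p at n = 13."""
        from scipy import stats as sps

        pred, obs = rng.normal(size=13), rng.normal(size=13)
        res = eq.evaluate(pred, obs)
        pc, oc = pred - pred.mean(), obs - obs.mean()
        r = (pc @ oc) / np.sqrt((pc @ pc) * (oc @ oc))
        t = r * np.sqrt(11 / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), 11)
        assert res.pearson_r == pytest.approx(r, abs=1e-12)
        assert res.r_squared == pytest.approx(r * r, abs=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)
        assert res.n == 13 and len(res.pairs) == 13

    def test_constant_predictions_rejected(self):
        with pytest.raises(DegenerateInputError):
            eq.evaluate(np.ones(5), np.arange(5.0))


class TestKktOracle:
    def test_residual_flags_perturbed_solutions(self, rng):
        X, _, _ = standardize(rng.normal(size=(30, 6)))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        intercept, coef, _, _ = fit_enet(X, y, l1_ratio=0.7, lam=0.1)
        good = kkt_residual(X, y, intercept, coef, 0.7, 0.1)
        bad = kkt_residual(X, y, intercept, coef + 0.05, 0.7, 0.1)
        assert good < 1e-8 < bad
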