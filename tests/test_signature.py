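import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from bactexclude.datatypes import ExpressionMatrix, PipelineError
from bactexclude.signature import (
    TransformSpec,
    TuningGrid,
    _grid_models,
    default_lambda_path,
    fit_final_signature,
    fit_lasso_logistic_path,
    hard_threshold,
    inner_lobo_tune,
    kkt_gap,
    lambda_max,
    lasso_logistic_objective,
    nested_lobo_cv,
    relax_fit,
    transform_expression,
)
from bactexclude.simulate import generate_cohort
from conftest import cohort_arrays, recovery_config
from oracles import lasso_logistic_min_objective


def _instance(rng, n=50, p=12, signal=3):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[:signal] = rng.normal(0, 1.2, signal)
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


class TestTransform:
    def test_fit_mode_standardizes(self, rng):
        cpm = pd.DataFrame(
            rng.integers(1, 500, size=(20, 15)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(15)],
        )
        Xs, spec = transform_expression(ExpressionMatrix(cpm, "cpm"))
        np.testing.assert_allclose(Xs.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0), 1, atol=1e-9)
        # scoring mode with the fitted spec reproduces fit mode
        Xs2, _ = transform_expression(ExpressionMatrix(cpm, "cpm"), spec)
        np.testing.assert_allclose(Xs, Xs2)

    def test_constant_gene_floored(self):
        cpm = pd.DataFrame(
            [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "var"],
            columns=["a", "b", "c"],
        )
        Xs, spec = transform_expression(ExpressionMatrix(cpm, "cpm"))
        np.testing.assert_allclose(Xs[:, 0], 0.0)
        assert spec.scale[0] > 0

    def test_missing_gene_raises(self):
        cpm = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["a", "b"])
        spec = TransformSpec(np.zeros(2), np.ones(2), ["g0", "absent"])
        with pytest.raises(PipelineError, match="absent"):
            transform_expression(ExpressionMatrix(cpm, "cpm"), spec)


class TestLassoPath:
    def test_above_lambda_max_gives_null_model(self, rng):
        X, y = _instance(rng)
        lmax = lambda_max(X, y)
        B0, B = fit_lasso_logistic_path(X, y, np.array([lmax * 1.0001]))
        assert np.all(B == 0)
        assert B0[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)

    def test_kkt_conditions_along_path(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = _instance(rng, n=60, p=15)
            lams = default_lambda_path(X, y, 12, 0.01)
            B0, B = fit_lasso_logistic_path(X, y, lams)
            for i, lam in enumerate(lams):
                assert kkt_gap(X, y, B0[i], B[i], lam) <= 1e-6

    def test_objective_matches_generic_convex_solver(self, rng):
        X, y = _instance(rng, n=40, p=10)
        lams = default_lambda_path(X, y, 5, 0.05)
        B0, B = fit_lasso_logistic_path(X, y, lams)
        for i in (0, 2, 4):
            ours = lasso_logistic_objective(X, y, B0[i], B[i], lams[i])
            ref = lasso_logistic_min_objective(X, y, lams[i])
            assert ours <= ref + 1e-6

    def test_duplicated_feature_column_still_optimal(self, rng):
        X, y = _instance(rng, n=40, p=6)
        X = np.column_stack([X, X[:, 0]])  # exact duplicate
        lams = default_lambda_path(X, y, 4, 0.1)
        B0, B = fit_lasso_logistic_path(X, y, lams)
        for i in range(4):
            ours = lasso_logistic_objective(X, y, B0[i], B[i], lams[i])
            ref = lasso_logistic_min_objective(X, y, lams[i])
            assert abs(ours - ref) < 1e-5

    def test_rejects_bad_inputs(self, rng):
        X, y = _instance(rng)
        with pytest.raises(PipelineError):
            fit_lasso_logistic_path(X, y, np.array([0.1, 0.2]))  # increasing
        with pytest.raises(PipelineError):
            fit_lasso_logistic_path(X, np.zeros_like(y), np.array([0.1]))


class TestRelaxAndThreshold:
    def test_gamma_one_recovers_lasso(self, rng):
        X, y = _instance(rng)
        lam = lambda_max(X, y) * 0.3
        B0, B = fit_lasso_logistic_path(
            X, y, np.geomspace(lambda_max(X, y), lam, 6)
        )
        support = np.flatnonzero(B[-1])
        b0, beta = relax_fit(X, y, support, 1.0, lam, lasso=(B0[-1], B[-1]))
        np.testing.assert_allclose(beta, B[-1][support])
        assert b0 == pytest.approx(B0[-1])

    def test_gamma_zero_matches_ml_refit(self, rng):
        X, y = _instance(rng, n=200, p=8, signal=2)
        lam = lambda_max(X, y) * 0.5
        b0, beta = relax_fit(X, y, np.array([0, 1]), 0.0, lam)
        ref = LogisticRegression(C=np.inf, tol=1e-12, max_iter=10000)
        ref.fit(X[:, [0, 1]], y)
        np.testing.assert_allclose(beta, ref.coef_[0], atol=1e-6)
        assert b0 == pytest.approx(ref.intercept_[0], abs=1e-6)

    def test_empty_support_gives_intercept_only(self, rng):
        X, y = _instance(rng)
        b0, beta = relax_fit(X, y, np.array([], dtype=int), 0.0, 0.1)
        assert len(beta) == 0
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_hard_threshold_examples(self):
        beta = np.array([0.5, 0.001])
        out, changed = hard_threshold(beta, 0.01)
        assert out.tolist() == [0.5, 0.0] and changed
        out, changed = hard_threshold(beta, 0.0)
        assert np.array_equal(out, beta) and not changed
        out, _ = hard_threshold(beta, 10.0)
        assert np.all(out == 0)
        with pytest.raises(PipelineError):
            hard_threshold(beta, -1.0)

    def test_support_size_monotone_in_tau(self, rng):
        X, y = _instance(rng, n=80, p=20, signal=5)
        lams = default_lambda_path(X, y, 8, 0.02)
        grid = TuningGrid(taus=(0.0, 0.02, 0.05, 0.1, 0.3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = _grid_models(X, y, lams, grid)
        for li in range(8):
            for gi in range(len(grid.gammas)):
                sizes = [
                    len(models[(li, gi, ti)][1])
                    for ti in range(len(grid.taus))
                    if models[(li, gi, ti)] is not None
                ]
                assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestLoboTuning:
    @pytest.fixture(scope="class")
    def cohort(self):
        cfg = recovery_config(seed=17, n_genes=500, n_samples=180)
        cm, ann, truth = generate_cohort(cfg)
        X_log, y, batches, genes = cohort_arrays(cm, ann)
        return X_log, y, batches, genes, truth

    def test_single_point_grid_returned(self, cohort):
        X_log, y, batches, *_ = cohort
        grid = TuningGrid(n_lambda=1, lambda_min_ratio=0.5, gammas=(0.25,), taus=(0.1,))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen = inner_lobo_tune(X_log, y, batches, grid)
        assert chosen["gamma"] == 0.25 and chosen["tau"] == 0.1

    def test_final_fit_recovers_planted_genes(self, cohort):
        X_log, y, batches, genes, truth = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_final_signature(X_log, y, batches, gene_names=genes)
        assert 1 <= len(model.genes) <= 6
        assert len(set(model.genes) & set(truth.signature_genes)) >= 3
        # signs: bacterial-elevated genes positive, interferon-like negative
        for g, b in zip(model.genes, model.beta):
            if g in truth.signature_genes[:3]:
                assert b > 0
            if g == truth.signature_genes[3]:
                assert b < 0

    def test_final_fit_is_deterministic(self, cohort):
        X_log, y, batches, genes, _ = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = fit_final_signature(X_log, y, batches, gene_names=genes)
            m2 = fit_final_signature(X_log, y, batches, gene_names=genes)
        assert m1.to_json() == m2.to_json()

    def test_nested_cv_partitions_samples(self, cohort):
        X_log, y, batches, *_ = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = nested_lobo_cv(X_log, y, batches)
        total = sum(len(f.scores) for f in cv.folds)
        assert total == len(y)  # each sample held out exactly once
        held_batches = [f.batch for f in cv.folds]
        assert len(set(held_batches)) == len(held_batches)
        assert 0.5 < cv.pooled_auc <= 1.0

    def test_fold_model_ignores_its_held_out_batch(self, cohort):
        # leakage check: corrupting a held-out batch must not change the
        # model that scores it (trained on the other batches)
        X_log, y, batches, *_ = cohort
        b = np.unique(batches)[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv1 = nested_lobo_cv(X_log, y, batches)
            X_corrupt = X_log.copy()
            rng = np.random.default_rng(0)
            X_corrupt[batches == b] += rng.normal(0, 3, size=X_corrupt[batches == b].shape)
            y_corrupt = y.copy()
            y_corrupt[batches == b] = rng.permutation(y_corrupt[batches == b])
            cv2 = nested_lobo_cv(X_corrupt, y_corrupt, batches)
        f1 = next(f for f in cv1.folds if f.batch == b)
        f2 = next(f for f in cv2.folds if f.batch == b)
        assert f1.tuning == f2.tuning
        assert f1.support_genes == f2.support_genes
        np.testing.assert_allclose(f1.beta, f2.beta)
        assert f1.intercept == pytest.approx(f2.intercept)

    def test_too_few_batches_rejected(self, cohort):
        X_log, y, *_ = cohort
        two = np.array(["a", "b"] * (len(y) // 2) + ["a"] * (len(y) % 2))
        with pytest.raises(PipelineError, match="batches"):
            nested_lobo_cv(X_log, y, two)

    def test_pure_noise_cohort_behaves_null(self):
        rng = np.random.default_rng(42)
        n, p = 140, 300
        X_log = rng.normal(5, 1, size=(n, p))
        y = np.array([0, 1] * (n // 2))
        batches = np.repeat([f"b{i}" for i in range(7)], n // 7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_final_signature(X_log, y, batches, gene_names=None)
            cv = nested_lobo_cv(X_log, y, batches)
        assert len(model.genes) <= 6  # budget respected, intercept-only allowed
        assert 0.3 < cv.pooled_auc < 0.7


def test_tuning_grid_validation():
    with pytest.raises(PipelineError):
        TuningGrid(gammas=())
    with pytest.raises(PipelineError):
        TuningGrid(gammas=(0.0, 1.5))
    with pytest.raises(PipelineError):
        TuningGrid(taus=(-0.1,))
    with pytest.raises(PipelineError):
        TuningGrid(lambdas=(0.1, 0.2))
    g = TuningGrid(lambdas=(0.2, 0.1, 0.05))
    assert g.lambda_path(np.zeros((2, 2)), np.array([0.0, 1.0])).tolist() == [0.2, 0.1, 0.05]
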