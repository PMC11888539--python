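import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bactexclude.datatypes import ExpressionMatrix, PipelineError
from bactexclude.evaluate import (
    classify,
    evaluate_external,
    npv_at_prevalence,
    ppv_at_prevalence,
    risk_score,
    roc_auc,
    threshold_for_sensitivity,
)
from bactexclude.preprocess import compute_cpm
from bactexclude.signature import SignatureModel, TransformSpec, fit_final_signature
from bactexclude.simulate import generate_cohort, generate_validation_cohort
from conftest import cohort_arrays, recovery_config
from oracles import auc_pairwise, threshold_exhaustive


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([2.0, 3.0, 1.0]), np.array([1, 1, 0]))
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc(np.ones(10), np.array([0, 1] * 5))
        assert auc == 0.5

    def test_matches_pairwise_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(PipelineError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_threshold_rule_lies_on_roc_curve(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[0], labels[1] = 0, 1
        points, _ = roc_auc(scores, labels)
        for t in np.unique(scores)[::7]:
            rep = classify(scores, labels, t)
            match = points[np.isclose(points["threshold"], t)]
            assert len(match) == 1
            assert rep.sensitivity == pytest.approx(match["tpr"].iloc[0])
            assert 1 - rep.specificity == pytest.approx(match["fpr"].iloc[0])


class TestPredictiveValues:
    def test_published_operating_point(self):
        # Se 90%, Sp 71%: NPV rounds to 91% at 40% prevalence and exceeds
        # 95% below 25% prevalence
        assert round(100 * npv_at_prevalence(0.90, 0.71, 0.40)) == 91
        assert npv_at_prevalence(0.90, 0.71, 0.25) > 0.95

    def test_limit_cases(self):
        assert npv_at_prevalence(1.0, 0.3, 0.7) == 1.0
        assert npv_at_prevalence(0.9, 0.71, 0.0) == 1.0
        assert npv_at_prevalence(1.0, 0.5, 1.0) == 0.0  # denominator vanishes
        assert ppv_at_prevalence(0.9, 0.71, 1.0) == 1.0
        assert ppv_at_prevalence(0.0, 1.0, 0.0) == 0.0

    @given(
        se=st.floats(0.01, 1.0),
        sp=st.floats(0.01, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_npv_monotone_nonincreasing_in_prevalence(self, se, sp):
        grid = np.linspace(0.0, 0.99, 25)
        npv = [npv_at_prevalence(se, sp, p) for p in grid]
        ppv = [ppv_at_prevalence(se, sp, p) for p in grid]
        assert all(a >= b - 1e-12 for a, b in zip(npv, npv[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(ppv, ppv[1:]))
        assert npv[0] == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(PipelineError):
            npv_at_prevalence(1.2, 0.5, 0.5)


class TestThresholdForSensitivity:
    def test_enumerated_example(self):
        scores = np.array([3.0, 2.0, 1.0, 0.0])
        labels = np.array([1, 1, 1, 0])
        rep = threshold_for_sensitivity(scores, labels, 0.9)
        assert rep.threshold == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 0, 1, 0)

    def test_target_one_forces_min_positive_score(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        rep = threshold_for_sensitivity(scores, labels, 1.0)
        assert rep.threshold == scores[labels == 1].min()
        assert rep.sensitivity == 1.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]  # both classes present (op precondition)
            target = float(rng.choice([0.5, 0.8, 0.9, 0.95, 1.0]))
            rep = threshold_for_sensitivity(scores, labels, target)
            se, sp, conf = threshold_exhaustive(scores, labels, target)
            assert rep.sensitivity == pytest.approx(se)
            assert rep.specificity == pytest.approx(sp)
            assert (rep.tp, rep.fp, rep.tn, rep.fn) == conf

    def test_no_positives_rejected(self):
        with pytest.raises(PipelineError):
            threshold_for_sensitivity(np.array([1.0, 2.0]), np.array([0, 0]), 0.9)

    def test_npv_at_40_prevalence_in_report(self):
        scores = np.concatenate([np.arange(10) + 2.0, np.arange(10) * 0.5])
        labels = np.array([1] * 10 + [0] * 10)
        rep = threshold_for_sensitivity(scores, labels, 0.9)
        want = npv_at_prevalence(rep.sensitivity, rep.specificity, 0.4)
        assert rep.npv_by_prevalence[0.4] == pytest.approx(want)


class TestClassify:
    def test_extreme_thresholds(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        rep_low = classify(scores, labels, -1e30)
        assert rep_low.sensitivity == 1.0 and rep_low.specificity == 0.0
        rep_high = classify(scores, labels, scores.max() + 1)
        assert rep_high.tp == 0 and rep_high.fn == labels.sum()

    def test_unlabeled_controls_fraction_tracks_specificity(self, rng):
        neg = rng.normal(0, 1, 4000)
        t = float(np.quantile(neg, 0.75))  # Sp = 0.75 by construction
        out = classify(rng.normal(0, 1, 4000), None, t)
        assert out["fraction_nonbacterial"] == pytest.approx(0.75, abs=0.03)
        assert out["fraction_bacterial"] + out["fraction_nonbacterial"] == 1.0

    def test_infinite_threshold_rejected(self, rng):
        with pytest.raises(PipelineError):
            classify(rng.normal(size=5), None, np.inf)


class TestRiskScoreAndExternal:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = recovery_config(seed=23, n_genes=400, n_samples=150)
        cm, ann, truth = generate_cohort(cfg)
        X_log, y, batches, genes = cohort_arrays(cm, ann)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_final_signature(X_log, y, batches, gene_names=genes)
        cpm = compute_cpm(cm)
        ari = ann.binary_labels().index
        expr = ExpressionMatrix(cpm.values[ari], "cpm")
        return cfg, cm, ann, truth, model, expr, y

    def test_empty_model_scores_intercept(self):
        model = SignatureModel(
            genes=[], intercept=-1.5, beta=np.zeros(0),
            transform=TransformSpec(np.zeros(0), np.ones(0), []),
            tuning={"lambda": 1.0, "gamma": 0.0, "tau": 0.0},
        )
        cpm = pd.DataFrame([[10.0, 20.0]], index=["g0"], columns=["a", "b"])
        s = risk_score(model, ExpressionMatrix(cpm, "cpm"))
        assert (s == -1.5).all()

    def test_scoring_is_deterministic(self, fitted):
        *_, model, expr, y = fitted
        s1 = risk_score(model, expr)
        s2 = risk_score(model, expr)
        assert (s1 == s2).all()

    def test_missing_gene_named_in_error(self, fitted):
        *_, model, expr, y = fitted
        dropped = ExpressionMatrix(expr.values.drop(index=model.genes[0]), "cpm")
        with pytest.raises(PipelineError, match=model.genes[0]):
            risk_score(model, dropped)

    def test_external_identity_reproduces_training_auc(self, fitted):
        _, _, _, _, model, expr, y = fitted
        train_auc = roc_auc(risk_score(model, expr).to_numpy(), y)[1]
        out = evaluate_external(model, expr, y, refit_transform=False)
        assert out["auc"] == pytest.approx(train_auc)

    def test_external_transfer_and_null(self, fitted):
        cfg, cm, ann, truth, model, expr, y = fitted
        vcm, vann = generate_validation_cohort(truth, cfg, seed=77)
        vy = vann.binary_labels().to_numpy()
        out = evaluate_external(model, compute_cpm(vcm), vy)
        train_auc = roc_auc(risk_score(model, expr).to_numpy(), y)[1]
        assert abs(out["auc_refit_transform"] - train_auc) < 0.1
        # signal-free cohort: nothing transfers
        v0, a0 = generate_validation_cohort(truth, cfg, seed=77, effect_scale=0.0)
        out0 = evaluate_external(model, compute_cpm(v0), a0.binary_labels().to_numpy())
        assert abs(out0["auc"] - 0.5) < 0.12

    def test_global_count_rescaling_cancels_in_cpm(self, fitted):
        cfg, cm, ann, truth, model, expr, y = fitted
        scaled = ExpressionMatrix(expr.values * 1.0, "cpm")  # identical CPM
        from bactexclude.datatypes import CountMatrix

        cm10 = CountMatrix(cm.counts * 10)
        ari = ann.binary_labels().index
        expr10 = ExpressionMatrix(compute_cpm(cm10).values[ari], "cpm")
        np.testing.assert_allclose(
            risk_score(model, expr10), risk_score(model, scaled)
        )
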