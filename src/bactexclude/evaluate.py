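"""Risk scoring, ROC/AUC, sensitivity-anchored thresholding and predictive
values over prevalence.

The classification rule throughout is: score >= threshold => bacterial.
The operating threshold is chosen as the largest threshold whose
sensitivity still meets the target floor, which maximizes specificity
subject to that floor. NPV and PPV are reported as functions of assumed
prevalence via the standard Bayes identities; with a rule-out test the
quantity of interest is NPV across the plausible prevalence range.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, PipelineError

if TYPE_CHECKING:  # pragma: no cover
    from .signature import SignatureModel

DEFAULT_PREVALENCE_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct score and the Mann--Whitney AUC.

    AUC equals the probability a random positive outscores a random
    negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise PipelineError("scores and labels must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise PipelineError("both classes required for ROC analysis")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.unique(scores)[::-1]
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    se = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="left") / n_neg
    points = pd.DataFrame(
        {"threshold": np.concatenate([[np.inf], thresholds]),
         "tpr": np.concatenate([[0.0], se]),
         "fpr": np.concatenate([[0.0], fpr])}
    )
    return points, float(auc)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann--Whitney AUC only (ties 1/2), without the ROC point table."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise PipelineError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def npv_at_prevalence(se: float, sp: float, prevalence: float) -> float:
    """NPV = sp(1-pi) / (sp(1-pi) + (1-se) pi); defined as 0 when the
    denominator vanishes (pi = 1 with perfect sensitivity)."""
    for v in (se, sp, prevalence):
        if not 0 <= v <= 1:
            raise PipelineError("se, sp and prevalence must lie in [0, 1]")
    denom = sp * (1 - prevalence) + (1 - se) * prevalence
    if denom == 0:
        return 0.0
    return sp * (1 - prevalence) / denom


def ppv_at_prevalence(se: float, sp: float, prevalence: float) -> float:
    """PPV = se pi / (se pi + (1-sp)(1-pi)); 0 when the denominator vanishes."""
    for v in (se, sp, prevalence):
        if not 0 <= v <= 1:
            raise PipelineError("se, sp and prevalence must lie in [0, 1]")
    denom = se * prevalence + (1 - sp) * (1 - prevalence)
    if denom == 0:
        return 0.0
    return se * prevalence / denom


@dataclass
class ThresholdReport:
    """Operating point of the rule "score >= t => bacterial"."""

    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    npv_by_prevalence: dict[float, float] = field(default_factory=dict)
    ppv_by_prevalence: dict[float, float] = field(default_factory=dict)

    @property
    def rule(self) -> str:
        return (
            f"score >= {self.threshold:.6g} => bacterial; "
            f"score < {self.threshold:.6g} => nonbacterial"
        )

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "npv_by_prevalence": {str(k): v for k, v in self.npv_by_prevalence.items()},
            "ppv_by_prevalence": {str(k): v for k, v in self.ppv_by_prevalence.items()},
            "rule": self.rule,
        }


def threshold_for_sensitivity(
    scores: np.ndarray,
    labels: np.ndarray,
    target_se: float = 0.90,
    prevalence_grid: tuple[float, ...] = DEFAULT_PREVALENCE_GRID,
) -> ThresholdReport:
    """Largest threshold whose sensitivity meets the floor.

    Since specificity is non-decreasing in the threshold, the largest
    threshold with Se >= target maximizes specificity subject to the floor.
    Candidate thresholds are the distinct observed scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not 0 < target_se <= 1:
        raise PipelineError("target sensitivity must lie in (0, 1]")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0:
        raise PipelineError("no positive samples; target sensitivity unachievable")
    candidates = np.unique(pos)[::-1]  # only positive scores can change Se
    t = None
    for c in candidates:
        if (pos >= c).mean() >= target_se:
            t = float(c)
            break
    if t is None:  # only possible if target > 1 handled above; lowest score works
        t = float(pos.min())
    return classify(scores, labels, t, prevalence_grid)


def classify(
    scores: np.ndarray,
    labels: np.ndarray | None,
    threshold: float,
    prevalence_grid: tuple[float, ...] = DEFAULT_PREVALENCE_GRID,
):
    """Apply the rule score >= threshold => bacterial.

    With labels: a full :class:`ThresholdReport`. Without labels (e.g.
    non-infected controls): a dict with the call fractions only.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(threshold):
        raise PipelineError("threshold must be finite")
    calls = scores >= threshold
    if labels is None:
        return {
            "n": int(len(scores)),
            "fraction_bacterial": float(calls.mean()) if len(scores) else float("nan"),
            "fraction_nonbacterial": float((~calls).mean()) if len(scores) else float("nan"),
        }
    labels = np.asarray(labels)
    tp = int((calls & (labels == 1)).sum())
    fp = int((calls & (labels == 0)).sum())
    tn = int((~calls & (labels == 0)).sum())
    fn = int((~calls & (labels == 1)).sum())
    se = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    have_both = np.isfinite(se) and np.isfinite(sp)
    return ThresholdReport(
        threshold=float(threshold),
        sensitivity=se,
        specificity=sp,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        npv_by_prevalence=(
            {p: npv_at_prevalence(se, sp, p) for p in prevalence_grid} if have_both else {}
        ),
        ppv_by_prevalence=(
            {p: ppv_at_prevalence(se, sp, p) for p in prevalence_grid} if have_both else {}
        ),
    )


def risk_score(model: "SignatureModel", expr: ExpressionMatrix) -> pd.Series:
    """Deterministic linear risk score of every sample in ``expr`` (CPM scale)."""
    expr.require_scale("cpm")
    return pd.Series(model.score_cpm(expr), index=expr.samples, name="risk_score")


def evaluate_external(
    model: "SignatureModel",
    expr_ext: ExpressionMatrix,
    labels_ext: np.ndarray,
    refit_transform: bool = False,
) -> dict:
    """Score an independently processed cohort and report its AUC.

    Both transform handlings are reported: coefficients applied through the
    training-data centering/scaling (``carried``) and through constants
    refit on the external cohort itself (``refit``); ``refit_transform``
    selects which one populates ``auc``/``scores``. Refitting makes the
    score invariant to global rescaling of the external data.
    """
    from .preprocess import LOG_PSEUDOCOUNT
    from .signature import TransformSpec

    labels_ext = np.asarray(labels_ext)
    scores_carried = risk_score(model, expr_ext)
    missing = [g for g in model.genes if g not in expr_ext.values.index]
    if missing:
        raise PipelineError(f"external cohort missing model genes: {missing}")
    sub = ExpressionMatrix(expr_ext.values.loc[model.genes], "cpm")
    X_log = np.log2(sub.values.to_numpy().T + LOG_PSEUDOCOUNT)
    spec_ext = TransformSpec.fit(X_log, model.genes)
    scores_refit = pd.Series(
        model.intercept + spec_ext.apply(X_log) @ model.beta,
        index=expr_ext.samples,
        name="risk_score",
    )
    auc_carried = roc_auc(scores_carried.to_numpy(), labels_ext)[1]
    auc_refit = roc_auc(scores_refit.to_numpy(), labels_ext)[1]
    chosen = scores_refit if refit_transform else scores_carried
    return {
        "auc": auc_refit if refit_transform else auc_carried,
        "auc_carried_transform": auc_carried,
        "auc_refit_transform": auc_refit,
        "scores": chosen,
        "transform_mode": "refit" if refit_transform else "carried",
    }
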