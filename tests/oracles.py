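"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation: the penalized
logistic objective is minimized by a generic bound-constrained quasi-Newton
solver on the split-variable reformulation, BH is the literal step-up
definition, AUC is O(n^2) pairwise counting, and the threshold search is
exhaustive over all cut-points.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def lasso_logistic_min_objective(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Minimum of mean logistic deviance + lam*||beta||_1 via a generic solver.

    Split-variable reformulation beta = bp - bn with bp, bn >= 0 makes the
    problem smooth and bound-constrained; solved with L-BFGS-B.
    """
    n, p = X.shape

    def fun(z):
        b0 = z[0]
        bp = z[1 : 1 + p]
        bn = z[1 + p :]
        beta = bp - bn
        eta = b0 + X @ beta
        ll = np.logaddexp(0.0, eta) - y * eta
        obj = ll.mean() + lam * (bp.sum() + bn.sum())
        pr = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        gb = X.T @ (pr - y) / n
        grad = np.concatenate([[np.mean(pr - y)], gb + lam, -gb + lam])
        return obj, grad

    z0 = np.zeros(1 + 2 * p)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        fun, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return float(res.fun)


def bh_stepup_brute(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini--Hochberg step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, i in enumerate(order):
        vals = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[i] = min(1.0, min(vals))
    return q


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) Mann--Whitney probability with ties counted 1/2."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_exhaustive(scores: np.ndarray, labels: np.ndarray, target_se: float):
    """Best operating point of "score >= t => bacterial" by brute force.

    Candidates: midpoints between sorted distinct scores, every distinct
    score, and +/- infinity. Returns (sensitivity, specificity, confusion)
    of the cut maximizing specificity subject to Se >= target (ties broken
    toward the larger threshold, which cannot change Se/Sp).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    cands = np.concatenate([[-np.inf], distinct, mids, [np.inf]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for t in cands:
        se = (pos >= t).mean()
        sp = (neg < t).mean()
        if se >= target_se:
            key = (sp, t)
            if best is None or key > best[0]:
                tp = int((pos >= t).sum())
                fn = len(pos) - tp
                fp = int((neg >= t).sum())
                tn = len(neg) - fp
                best = (key, se, sp, (tp, fp, tn, fn))
    assert best is not None
    return best[1], best[2], best[3]
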