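"""Sparse host-response signature estimation.

The estimator is a hard-thresholded, mostly relaxed, LASSO-constrained
logistic regression:

1. an L1-penalized logistic regression path (cyclic coordinate descent on
   the iteratively reweighted least-squares approximation, warm-started
   along a decreasing penalty sequence, intercept unpenalized);
2. relaxation: the fitted coefficients at penalty ``lam`` are blended with
   an unpenalized refit restricted to the active set,
   ``beta(gamma) = gamma * beta_lasso + (1 - gamma) * beta_refit`` —
   "mostly relaxed" means the tuning grid concentrates near ``gamma = 0``;
3. hard thresholding: blended standardized coefficients with magnitude
   below ``tau`` are zeroed and the surviving support is refit at the same
   ``gamma``.

Tuning of (lambda, gamma, tau) and performance estimation both use
leave-one-batch-out (LOBO) folds — sequencing batch, not random splits, is
the exchangeable unit — nested so that no held-out sample influences its
own scorer. Selection maximizes pooled held-out AUC subject to a sparsity
budget on the median support size; ties break toward sparser models, then
larger penalty, then smaller gamma.

Expression enters on the log2(CPM+1) scale as a samples-by-genes array and
is standardized per gene *inside* each training fold (the centering and
scaling constants are part of the model, never estimated on held-out data).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .datatypes import ExpressionMatrix, PipelineError
from .evaluate import auc_score, roc_auc
from .preprocess import LOG_PSEUDOCOUNT

SCALE_EPS = 1e-8
#: unpenalized refits are only attempted for supports up to this size;
#: larger supports keep the penalized coefficients (gamma effectively 1)
REFIT_SUPPORT_CAP = 30
_RIDGE_FALLBACK = 1e-6


class ConvergenceError(PipelineError):
    pass


# ---------------------------------------------------------------------------
# transform


@dataclass
class TransformSpec:
    """Per-gene centering/scaling constants of log2(CPM+1) training data."""

    center: np.ndarray
    scale: np.ndarray
    genes: list[str] | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise PipelineError("transform scales must be positive")

    @classmethod
    def fit(cls, X_log: np.ndarray, genes: list[str] | None = None) -> "TransformSpec":
        center = X_log.mean(axis=0)
        scale = X_log.std(axis=0, ddof=0)
        return cls(center, np.maximum(scale, SCALE_EPS), genes)

    def apply(self, X_log: np.ndarray) -> np.ndarray:
        return (X_log - self.center) / self.scale

    def restrict(self, idx: np.ndarray) -> "TransformSpec":
        genes = [self.genes[i] for i in idx] if self.genes is not None else None
        return TransformSpec(self.center[idx], self.scale[idx], genes)


def transform_expression(
    expr: ExpressionMatrix, spec: TransformSpec | None = None
) -> tuple[np.ndarray, TransformSpec]:
    """log2(CPM+1) then per-gene standardization; samples x genes output.

    With ``spec`` given (scoring mode) the stored constants are applied to
    the genes named in the spec; otherwise the transform is fit and
    returned alongside the standardized matrix.
    """
    expr.require_scale("cpm")
    if spec is None:
        X_log = np.log2(expr.values.to_numpy().T + LOG_PSEUDOCOUNT)
        fitted = TransformSpec.fit(X_log, list(expr.genes))
        return fitted.apply(X_log), fitted
    if spec.genes is not None:
        missing = [g for g in spec.genes if g not in expr.values.index]
        if missing:
            raise PipelineError(f"expression matrix missing model genes: {missing}")
        vals = expr.values.loc[spec.genes].to_numpy().T
    else:
        vals = expr.values.to_numpy().T
    X_log = np.log2(vals + LOG_PSEUDOCOUNT)
    return spec.apply(X_log), spec


# ---------------------------------------------------------------------------
# L1-penalized logistic path (coordinate descent on IRLS approximations)


@njit(cache=True)
def _solve_restricted(XT, y, lam, cand, beta, b0, eta, cd_tol, max_irls, max_sweeps):
    """Solve the L1 logistic problem exactly over the candidate columns.

    IRLS with cyclic coordinate descent on the weighted least-squares
    approximation; beta and eta are updated in place, the intercept is
    returned. Columns outside ``cand`` are untouched.
    """
    p, n = XT.shape
    nc = cand.shape[0]
    pr = np.empty(n)
    w = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)
    for irls in range(max_irls):
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            pi = 1.0 / (1.0 + np.exp(-e))
            if pi < 1e-7:
                pi = 1e-7
            elif pi > 1.0 - 1e-7:
                pi = 1.0 - 1e-7
            wi = pi * (1.0 - pi)
            pr[i] = pi
            w[i] = wi
            z[i] = eta[i] + (y[i] - pi) / wi
            r[i] = z[i] - eta[i]
        wsum = 0.0
        for i in range(n):
            wsum += w[i]
        for sweep in range(max_sweeps):
            maxd = 0.0
            u = 0.0
            for i in range(n):
                u += w[i] * r[i]
            db0 = u / wsum
            if db0 != 0.0:
                b0 += db0
                for i in range(n):
                    r[i] -= db0
                if abs(db0) > maxd:
                    maxd = abs(db0)
            for c in range(nc):
                j = cand[c]
                bj = beta[j]
                wxx = 0.0
                u = 0.0
                for i in range(n):
                    wx = w[i] * XT[j, i]
                    wxx += wx * XT[j, i]
                    u += wx * r[i]
                d = wxx / n
                if d <= 0.0:
                    continue
                u = u / n + d * bj
                if u > lam:
                    bnew = (u - lam) / d
                elif u < -lam:
                    bnew = (u + lam) / d
                else:
                    bnew = 0.0
                diff = bnew - bj
                if diff != 0.0:
                    for i in range(n):
                        r[i] -= diff * XT[j, i]
                    beta[j] = bnew
                    if abs(diff) > maxd:
                        maxd = abs(diff)
            if maxd < cd_tol:
                break
        maxde = 0.0
        maxe = 1.0
        for i in range(n):
            e_new = z[i] - r[i]
            d = abs(e_new - eta[i])
            if d > maxde:
                maxde = d
            if abs(e_new) > maxe:
                maxe = abs(e_new)
            eta[i] = e_new
        if maxde < 1e-10 * maxe:
            break
    return b0


def _lasso_path(X, XT, y, lambdas, cd_tol=1e-12, max_irls=200, max_sweeps=2000,
                dfmax=None):
    """Penalty path via sequential strong rules with exact KKT verification.

    Per penalty value: coordinate descent restricted to the strong-rule
    candidate set, then a full-gradient KKT check (one BLAS matvec) adds
    any violators and the restricted solve repeats until none remain.
    With ``dfmax`` set, the path stops once a solution's support exceeds it
    (the overfit tail is never a candidate under a sparsity budget);
    returns (intercepts, coefficients, number of penalties solved).
    """
    p, n = XT.shape
    nl = len(lambdas)
    B = np.zeros((nl, p))
    B0 = np.zeros(nl)
    ybar = y.mean()
    b0 = float(np.log(ybar / (1.0 - ybar)))
    beta = np.zeros(p)
    eta = np.full(n, b0)
    pr = 1.0 / (1.0 + np.exp(-eta))
    g = X.T @ (pr - y) / n
    lam_prev = float(np.max(np.abs(g)))
    n_solved = 0
    for li, lam in enumerate(lambdas):
        strong = np.abs(g) >= 2.0 * lam - lam_prev
        cand = np.flatnonzero(strong | (beta != 0))
        for _ in range(100):
            b0 = _solve_restricted(
                XT, y, lam, cand, beta, b0, eta, cd_tol, max_irls, max_sweeps
            )
            pr = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            g = X.T @ (pr - y) / n
            in_cand = np.zeros(p, dtype=bool)
            in_cand[cand] = True
            viol = np.flatnonzero(~in_cand & (np.abs(g) > lam * (1 + 1e-12) + 1e-12))
            if len(viol) == 0:
                break
            cand = np.union1d(cand, viol)
        B[li] = beta
        B0[li] = b0
        lam_prev = lam
        n_solved = li + 1
        if dfmax is not None and int((beta != 0).sum()) > dfmax:
            break
    return B0, B, n_solved


def lasso_logistic_objective(
    X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, lam: float
) -> float:
    """Mean logistic deviance plus L1 penalty (intercept unpenalized)."""
    eta = b0 + X @ beta
    # log(1 + e^eta) - y*eta, computed stably
    ll = np.logaddexp(0.0, eta) - y * eta
    return float(ll.mean() + lam * np.abs(beta).sum())


def kkt_gap(X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, lam: float) -> float:
    """Max violation of the subgradient optimality conditions."""
    eta = b0 + X @ beta
    pr = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    g = X.T @ (pr - y) / len(y)
    g0 = abs(float(np.mean(pr - y)))
    active = beta != 0
    gap = g0
    if active.any():
        gap = max(gap, float(np.max(np.abs(g[active] + lam * np.sign(beta[active])))))
    if (~active).any():
        gap = max(gap, float(np.max(np.maximum(np.abs(g[~active]) - lam, 0.0))))
    return gap


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def default_lambda_path(
    X: np.ndarray, y: np.ndarray, n_lambda: int = 20, min_ratio: float = 0.02
) -> np.ndarray:
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def fit_lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float],
    *,
    kkt_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path for the L1-penalized logistic regression.

    Returns (intercepts, coefficients) with one row per penalty value;
    penalties must be strictly decreasing. Solutions are verified against
    the KKT conditions; persistent violation raises :class:`ConvergenceError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas <= 0) or np.any(np.diff(lambdas) >= 0):
        raise PipelineError("lambda path must be positive and strictly decreasing")
    if len(np.unique(y)) != 2 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise PipelineError("y must contain both classes, coded 0/1")
    XT = np.ascontiguousarray(X.T)
    B0, B, _ = _lasso_path(X, XT, y, lambdas)
    for li, lam in enumerate(lambdas):
        gap = kkt_gap(X, y, B0[li], B[li], lam)
        if gap > kkt_tol:
            raise ConvergenceError(
                f"lasso path did not converge at lambda={lam:.3e} (KKT gap {gap:.2e})"
            )
    return B0, B


# ---------------------------------------------------------------------------
# unpenalized refit / relaxation / thresholding


def _newton_logistic(
    Xs: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 40,
    tol: float = 1e-10,
    coef_cap: float = 60.0,
    init: np.ndarray | None = None,
) -> tuple[float, np.ndarray, bool]:
    """Maximum-likelihood logistic fit (optionally ridge-stabilized).

    Returns (intercept, coefficients, converged). Coefficients running past
    ``coef_cap`` (quasi-separation) end the fit early with
    ``converged = False``.
    """
    n, k = Xs.shape
    A = np.column_stack([np.ones(n), Xs])
    if init is not None:
        coef = init.copy()
    else:
        coef = np.zeros(k + 1)
        ybar = y.mean()
        coef[0] = np.log(ybar / (1 - ybar))
    pen = np.full(k + 1, ridge)
    pen[0] = 0.0
    pen_diag = np.diag(pen)

    def objective(c):
        eta = A @ c
        return float(np.mean(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * c**2))

    obj = objective(coef)
    for _ in range(max_iter):
        eta = A @ coef
        pr = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(pr * (1 - pr), 1e-10)
        grad = A.T @ (pr - y) / n + pen * coef
        H = (A.T * w) @ A / n + pen_diag
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return coef[0], coef[1:], False
        # damped Newton: halve the step until the objective stops increasing
        t = 1.0
        for _half in range(30):
            new = coef - t * step
            new_obj = objective(new)
            if new_obj <= obj + 1e-14:
                break
            t *= 0.5
        coef = coef - t * step
        obj = new_obj
        if np.max(np.abs(t * step)) < tol:
            return coef[0], coef[1:], True
        if np.max(np.abs(coef[1:])) > coef_cap:
            return coef[0], coef[1:], False
    return coef[0], coef[1:], False


def _refit_support(Xs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """ML refit on a support; falls back to a tiny ridge if separable."""
    if Xs.shape[1] == 0:
        ybar = y.mean()
        return float(np.log(ybar / (1 - ybar))), np.zeros(0)
    b0, beta, ok = _newton_logistic(Xs, y)
    if not ok or np.max(np.abs(beta)) > 50:
        warnings.warn("separable refit; using ridge-stabilized coefficients")
        init = np.clip(np.concatenate([[b0], beta]), -30, 30)
        b0, beta, ok = _newton_logistic(
            Xs, y, ridge=_RIDGE_FALLBACK, max_iter=500, coef_cap=np.inf, init=init
        )
        if not ok:
            raise ConvergenceError("ridge-stabilized refit did not converge")
    return float(b0), beta


def relax_fit(
    X: np.ndarray,
    y: np.ndarray,
    support: np.ndarray,
    gamma: float,
    lam: float,
    lasso: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Relaxed-lasso blend on a support.

    ``beta(gamma) = gamma * beta_lasso + (1 - gamma) * beta_refit`` where
    ``beta_refit`` is the unpenalized logistic fit restricted to the
    support. ``gamma = 1`` recovers the lasso fit (restricted to the
    support), ``gamma = 0`` the fully relaxed refit. The intercept is
    blended the same way. Returns (intercept, coefficients over support).

    ``lasso`` may carry a precomputed (intercept, full coefficient vector)
    solution at ``lam``; otherwise it is computed here.
    """
    if not 0.0 <= gamma <= 1.0:
        raise PipelineError("gamma must lie in [0, 1]")
    support = np.asarray(support, dtype=int)
    if lasso is None:
        path = np.geomspace(max(lambda_max(X, y), lam * 1.001), lam, 8)
        B0, B = fit_lasso_logistic_path(X, y, path)
        lasso = (float(B0[-1]), B[-1])
    b0_l, beta_l = lasso
    beta_l_s = np.asarray(beta_l)[support] if len(support) else np.zeros(0)
    if gamma == 1.0:
        return float(b0_l), beta_l_s.copy()
    b0_r, beta_r = _refit_support(X[:, support], y)
    return gamma * b0_l + (1 - gamma) * b0_r, gamma * beta_l_s + (1 - gamma) * beta_r


def hard_threshold(beta: np.ndarray, tau: float) -> tuple[np.ndarray, bool]:
    """Zero coefficients with |beta| < tau; returns (sparse beta, changed).

    ``changed`` signals that the surviving support should be refit (at the
    current relaxation weight). ``tau = 0`` is the identity.
    """
    if tau < 0:
        raise PipelineError("tau must be non-negative")
    out = np.where(np.abs(beta) >= tau, beta, 0.0)
    return out, bool(np.any(out != beta))


# ---------------------------------------------------------------------------
# tuning grid and model containers


@dataclass(frozen=True)
class TuningGrid:
    """(lambda, gamma, tau) search grid.

    The penalty path is either given explicitly (strictly decreasing) or
    derived per training set as ``n_lambda`` log-spaced values from the
    data's lambda_max down to ``lambda_min_ratio`` times it. The gamma grid
    concentrates near 0 ("mostly relaxed"); tau thresholds act on
    standardized-scale coefficients.
    """

    n_lambda: int = 20
    lambda_min_ratio: float = 0.02
    gammas: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 1.0)
    taus: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2)
    lambdas: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.gammas or not self.taus:
            raise PipelineError("gamma and tau grids must be non-empty")
        if any(g < 0 or g > 1 for g in self.gammas):
            raise PipelineError("gammas must lie in [0, 1]")
        if any(t < 0 for t in self.taus):
            raise PipelineError("taus must be non-negative")
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas)
            if len(lam) == 0 or np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
                raise PipelineError("lambdas must be positive, strictly decreasing")
        elif self.n_lambda < 1 or not 0 < self.lambda_min_ratio < 1:
            raise PipelineError("invalid lambda path parameters")

    def lambda_path(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.lambdas is not None:
            return np.asarray(self.lambdas, dtype=float)
        return default_lambda_path(X, y, self.n_lambda, self.lambda_min_ratio)


@dataclass
class SignatureModel:
    """A fitted sparse signature: genes, coefficients, transform, tuning.

    Coefficients are on the standardized log2(CPM+1) scale; the transform
    holds the training-data centering/scaling constants for exactly the
    selected genes, so the risk score is a pure function of the model and
    the raw CPM expression of its genes.
    """

    genes: list[str]
    intercept: float
    beta: np.ndarray
    transform: TransformSpec
    tuning: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.genes) != len(self.beta):
            raise PipelineError("genes and coefficients must align")
        if np.any(self.beta == 0):
            raise PipelineError("selected coefficients must be nonzero")

    def score_cpm(self, expr: ExpressionMatrix) -> np.ndarray:
        """Risk score beta0 + sum_j beta_j * standardized log2(CPM+1)."""
        Xs, _ = transform_expression(expr, self.transform)
        return self.intercept + Xs @ self.beta

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "beta": self.beta.tolist(),
                "intercept": self.intercept,
                "center": self.transform.center.tolist(),
                "scale": self.transform.scale.tolist(),
                "coefficient_scale": "standardized-log2cpm",
                "lambda": self.tuning.get("lambda"),
                "gamma": self.tuning.get("gamma"),
                "tau": self.tuning.get("tau"),
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        spec = TransformSpec(np.array(d["center"]), np.array(d["scale"]), list(d["genes"]))
        return cls(
            genes=list(d["genes"]),
            intercept=float(d["intercept"]),
            beta=np.array(d["beta"]),
            transform=spec,
            tuning={"lambda": d["lambda"], "gamma": d["gamma"], "tau": d["tau"]},
            metadata=d.get("metadata", {}),
        )


@dataclass
class FoldResult:
    batch: object
    scores: np.ndarray
    labels: np.ndarray
    tuning: dict
    support_genes: list[int]
    intercept: float = 0.0
    beta: np.ndarray | None = None


@dataclass
class CVResult:
    folds: list[FoldResult]
    pooled_auc: float
    per_fold_auc: list[float]

    @property
    def mean_fold_auc(self) -> float:
        vals = [a for a in self.per_fold_auc if np.isfinite(a)]
        return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# grid evaluation over LOBO folds


def _grid_models(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    grid: TuningGrid,
    dfmax: int | None = None,
) -> dict[tuple[int, int, int], tuple[float, np.ndarray, np.ndarray] | None]:
    """Fit every (lambda, gamma, tau) model on one training set.

    Returns {key: (intercept, support indices, coefficients)}; ``None``
    marks grid points skipped because the lasso support outgrew the refit
    cap or the dfmax path cutoff.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    XT = np.ascontiguousarray(X.T)
    B0, B, n_solved = _lasso_path(X, XT, y, lambdas, dfmax=dfmax)
    for li in range(n_solved):
        gap = kkt_gap(X, y, B0[li], B[li], lambdas[li])
        if gap > 1e-6:
            raise ConvergenceError(
                f"lasso path did not converge at lambda={lambdas[li]:.3e} (KKT gap {gap:.2e})"
            )
    refit_cache: dict[frozenset, tuple[float, np.ndarray]] = {}

    def refit(idx: np.ndarray) -> tuple[float, np.ndarray]:
        key = frozenset(idx.tolist())
        if key not in refit_cache:
            refit_cache[key] = _refit_support(X[:, idx], y)
        return refit_cache[key]

    models: dict[tuple[int, int, int], tuple[float, np.ndarray, np.ndarray] | None] = {}
    for li in range(len(lambdas)):
        if li >= n_solved:
            for gi in range(len(grid.gammas)):
                for ti in range(len(grid.taus)):
                    models[(li, gi, ti)] = None
            continue
        support = np.flatnonzero(B[li])
        beta_l = B[li][support]
        b0_l = float(B0[li])
        for gi, gamma in enumerate(grid.gammas):
            if gamma < 1.0 and len(support) > REFIT_SUPPORT_CAP:
                for ti in range(len(grid.taus)):
                    models[(li, gi, ti)] = None
                continue
            if gamma == 1.0:
                b0_g, beta_g = b0_l, beta_l
            else:
                b0_r, beta_r = refit(support)
                b0_g = gamma * b0_l + (1 - gamma) * b0_r
                beta_g = gamma * beta_l + (1 - gamma) * beta_r
            for ti, tau in enumerate(grid.taus):
                keep = np.abs(beta_g) >= tau
                idx = support[keep]
                if len(idx) == len(support):
                    models[(li, gi, ti)] = (b0_g, idx, beta_g.copy())
                    continue
                if gamma == 1.0:
                    models[(li, gi, ti)] = (b0_l, idx, B[li][idx])
                    continue
                b0_r2, beta_r2 = refit(idx)
                models[(li, gi, ti)] = (
                    gamma * b0_l + (1 - gamma) * b0_r2,
                    idx,
                    gamma * B[li][idx] + (1 - gamma) * beta_r2,
                )
    return models


def _lobo_grid_search(
    X_log: np.ndarray,
    y: np.ndarray,
    batches: np.ndarray,
    grid: TuningGrid,
    sparsity_budget: int | None,
) -> dict:
    """One level of LOBO tuning: fit the grid per fold, pool held-out AUCs.

    Returns the chosen tuning plus per-grid-point diagnostics.
    """
    ub = np.unique(batches)
    if len(ub) < 2:
        raise PipelineError("need at least 2 batches for LOBO tuning")
    # shared penalty path so grid points are comparable across folds
    spec_all = TransformSpec.fit(X_log)
    lambdas = grid.lambda_path(spec_all.apply(X_log), y.astype(float))
    dfmax = (
        None
        if sparsity_budget is None
        else max(REFIT_SUPPORT_CAP, 5 * sparsity_budget)
    )

    keys = [
        (li, gi, ti)
        for li in range(len(lambdas))
        for gi in range(len(grid.gammas))
        for ti in range(len(grid.taus))
    ]
    scores: dict[tuple, list[np.ndarray]] = {k: [] for k in keys}
    labels_pool: list[np.ndarray] = []
    supports: dict[tuple, list[int]] = {k: [] for k in keys}
    invalid: set[tuple] = set()
    n_folds = 0
    for b in ub:
        ho = batches == b
        tr = ~ho
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            warnings.warn(f"inner fold leaving out batch {b!r} empties a class; skipped")
            continue
        n_folds += 1
        spec = TransformSpec.fit(X_log[tr])
        Xtr = spec.apply(X_log[tr])
        Xho = spec.apply(X_log[ho])
        models = _grid_models(Xtr, ytr.astype(float), lambdas, grid, dfmax=dfmax)
        labels_pool.append(y[ho])
        for k in keys:
            m = models[k]
            if m is None:
                invalid.add(k)
                scores[k].append(np.zeros(int(ho.sum())))
                continue
            b0, idx, vals = m
            scores[k].append(b0 + Xho[:, idx] @ vals)
            supports[k].append(len(idx))
    if n_folds == 0:
        raise PipelineError("no usable LOBO tuning fold (every fold empties a class)")
    y_pool = np.concatenate(labels_pool)
    records = []
    for k in keys:
        if k in invalid:
            continue
        s = np.concatenate(scores[k])
        auc = auc_score(s, y_pool)
        med_support = float(np.median(supports[k]))
        records.append((k, auc, med_support))
    if not records:
        raise PipelineError("entire tuning grid invalid (supports exceed refit cap)")
    feasible = [r for r in records if sparsity_budget is None or r[2] <= sparsity_budget]
    if not feasible:
        # nothing meets the budget: fall back to the sparsest grid point
        min_support = min(r[2] for r in records)
        feasible = [r for r in records if r[2] == min_support]
    # maximize AUC; ties -> sparser, larger lambda (smaller index), smaller
    # gamma, larger tau
    def sort_key(rec):
        (li, gi, ti), auc, med = rec
        return (-auc, med, li, grid.gammas[gi], -grid.taus[ti])

    best = min(feasible, key=sort_key)
    (li, gi, ti), auc, med = best
    return {
        "lambda": float(lambdas[li]),
        "gamma": float(grid.gammas[gi]),
        "tau": float(grid.taus[ti]),
        "inner_auc": float(auc),
        "median_support": med,
        "lambda_index": li,
    }


def inner_lobo_tune(
    X_log: np.ndarray,
    y: np.ndarray,
    batches: np.ndarray,
    grid: TuningGrid = TuningGrid(),
    sparsity_budget: int | None = 6,
) -> dict:
    """Choose (lambda, gamma, tau) by leave-one-batch-out grid search.

    Maximizes pooled held-out AUC subject to median support size within the
    sparsity budget (budget ``None`` disables the constraint).
    """
    return _lobo_grid_search(
        np.asarray(X_log, float), np.asarray(y), np.asarray(batches), grid, sparsity_budget
    )


def _fit_tuned(
    X_log: np.ndarray, y: np.ndarray, tuning: dict, grid: TuningGrid
) -> tuple[TransformSpec, float, np.ndarray, np.ndarray]:
    """Fit one model on a full training set at a chosen (lambda, gamma, tau)."""
    spec = TransformSpec.fit(X_log)
    X = spec.apply(X_log)
    yf = y.astype(float)
    lam, gamma, tau = tuning["lambda"], tuning["gamma"], tuning["tau"]
    lmax = lambda_max(X, yf)
    if lam >= lmax:
        path = np.array([lam])
    else:
        path = np.geomspace(lmax, lam, 10)
    B0, B = fit_lasso_logistic_path(X, yf, path)
    b0_l, beta_full = float(B0[-1]), B[-1]
    support = np.flatnonzero(beta_full)
    if gamma < 1.0 and len(support) > REFIT_SUPPORT_CAP:
        warnings.warn("lasso support exceeds refit cap; keeping penalized coefficients")
        gamma = 1.0
    b0_g, beta_g = relax_fit(X, yf, support, gamma, lam, lasso=(b0_l, beta_full))
    thr, changed = hard_threshold(beta_g, tau)
    idx = support[thr != 0]
    if changed:
        b0_g, beta_g = relax_fit(X, yf, idx, gamma, lam, lasso=(b0_l, beta_full))
    else:
        beta_g = beta_g[thr != 0] if len(support) else beta_g
    return spec, float(b0_g), idx, np.asarray(beta_g)


def nested_lobo_cv(
    X_log: np.ndarray,
    y: np.ndarray,
    batches: np.ndarray,
    grid: TuningGrid = TuningGrid(),
    sparsity_budget: int | None = 6,
) -> CVResult:
    """Nested leave-one-batch-out CV of the whole tuning-plus-fitting procedure.

    For each outer batch: tune on the remaining batches (inner LOBO), fit
    the tuned model on those batches, score the held-out batch. The pooled
    AUC over all held-out scores estimates the performance of the
    procedure; no held-out sample influences its own scorer.
    """
    X_log = np.asarray(X_log, float)
    y = np.asarray(y)
    batches = np.asarray(batches)
    ub = np.unique(batches)
    if len(ub) < 3:
        raise PipelineError("nested LOBO CV requires at least 3 batches")
    folds = []
    for b in ub:
        ho = batches == b
        tr = ~ho
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"outer fold leaving out batch {b!r} empties a class; skipped")
            continue
        tuning = _lobo_grid_search(X_log[tr], y[tr], batches[tr], grid, sparsity_budget)
        spec, b0, idx, beta = _fit_tuned(X_log[tr], y[tr], tuning, grid)
        Xho = spec.apply(X_log[ho])
        folds.append(
            FoldResult(
                batch=b,
                scores=b0 + Xho[:, idx] @ beta,
                labels=y[ho],
                tuning=tuning,
                support_genes=idx.tolist(),
                intercept=b0,
                beta=beta.copy(),
            )
        )
    if not folds:
        raise PipelineError("no usable outer fold")
    pooled_scores = np.concatenate([f.scores for f in folds])
    pooled_labels = np.concatenate([f.labels for f in folds])
    pooled_auc = roc_auc(pooled_scores, pooled_labels)[1]
    per_fold = []
    for f in folds:
        if len(np.unique(f.labels)) == 2:
            per_fold.append(roc_auc(f.scores, f.labels)[1])
        else:
            per_fold.append(float("nan"))
    return CVResult(folds=folds, pooled_auc=float(pooled_auc), per_fold_auc=per_fold)


def fit_final_signature(
    X_log: np.ndarray,
    y: np.ndarray,
    batches: np.ndarray,
    grid: TuningGrid = TuningGrid(),
    sparsity_budget: int | None = 6,
    gene_names: Sequence[str] | None = None,
) -> SignatureModel:
    """Tune by (non-nested) LOBO over all batches, then fit on all data."""
    X_log = np.asarray(X_log, float)
    y = np.asarray(y)
    batches = np.asarray(batches)
    tuning = _lobo_grid_search(X_log, y, batches, grid, sparsity_budget)
    spec, b0, idx, beta = _fit_tuned(X_log, y, tuning, grid)
    if gene_names is None:
        gene_names = [f"feature{j}" for j in range(X_log.shape[1])]
    spec.genes = list(gene_names)
    nz = beta != 0
    idx = idx[nz]
    beta = beta[nz]
    return SignatureModel(
        genes=[gene_names[j] for j in idx],
        intercept=b0,
        beta=beta,
        transform=spec.restrict(idx),
        tuning=tuning,
        metadata={"n_samples": int(len(y)), "n_features": int(X_log.shape[1])},
    )
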