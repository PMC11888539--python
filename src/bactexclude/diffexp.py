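"""Two-group negative-binomial Wald differential expression.

A deliberately compact NB testing core for ranking genes by association with
the any-bacterial vs nonbacterial outcome: median-of-ratios size factors,
method-of-moments dispersions shrunk toward a parametric mean--dispersion
trend, a delta-method Wald test on the log2 fold change of group means, and
Benjamini--Hochberg FDR control. It implements the standard NB machinery
directly rather than the full GLM apparatus of dedicated DE packages (no
Cox--Reid adjustment, LFC shrinkage, independent filtering or outlier
refitting); it is a ranking stage, and its leave-one-batch-out consistency
summary, not a reference DE implementation.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, PipelineError, SampleAnnotation

DISPERSION_FLOOR = 1e-8
#: weight pulling per-gene dispersions toward the fitted trend (log scale)
TREND_SHRINKAGE = 0.25


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: the median over all-nonzero genes of count / geometric mean
    across samples. If no gene is nonzero in every sample, falls back to
    total-count ratios with a warning.
    """
    X = counts.counts.to_numpy(dtype=float)
    all_nonzero = (X > 0).all(axis=1)
    if all_nonzero.any():
        logs = np.log(X[all_nonzero])
        log_geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - log_geo, axis=0))
    else:
        warnings.warn("no gene with nonzero counts in all samples; using total-count ratios")
        tot = X.sum(axis=0)
        if (tot == 0).any():
            raise PipelineError("sample with zero total counts")
        sf = tot
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.samples, name="size_factor")


def _fit_dispersion_trend(mean_norm: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Parametric trend alpha(mu) = a0 + a1/mu fit to positive raw estimates."""
    ok = (alpha_raw > 10 * DISPERSION_FLOOR) & (mean_norm > 0)
    if ok.sum() < 10:
        return np.full_like(mean_norm, max(np.median(alpha_raw), DISPERSION_FLOOR))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean_norm[ok]])
    coef, *_ = np.linalg.lstsq(A, alpha_raw[ok], rcond=None)
    a0 = max(coef[0], DISPERSION_FLOOR)
    a1 = max(coef[1], 0.0)
    trend = a0 + a1 / np.maximum(mean_norm, 1e-8)
    return trend


def estimate_dispersions(
    counts: CountMatrix, sf: pd.Series, labels: pd.Series
) -> pd.Series:
    """Per-gene NB dispersion alpha with Var = mu + alpha mu^2.

    Method-of-moments within each label group on size-factor-normalized
    counts, pooled across groups, then shrunk toward a fitted a0 + a1/mu
    trend with fixed weight on the log scale. Floored at a small constant.
    """
    samples = labels.index
    X = counts.counts[samples].to_numpy(dtype=float) / sf.loc[samples].to_numpy()
    alpha_num = np.zeros(X.shape[0])
    alpha_den = 0.0
    for g in np.unique(labels):
        sub = X[:, (labels == g).to_numpy()]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        a = (v - m) / np.maximum(m, 1e-8) ** 2
        alpha_num += (n - 1) * np.maximum(a, 0.0)
        alpha_den += n - 1
    if alpha_den == 0:
        raise PipelineError("need at least 2 samples in some group")
    alpha_raw = np.maximum(alpha_num / alpha_den, DISPERSION_FLOOR)
    mean_norm = X.mean(axis=1)
    trend = _fit_dispersion_trend(mean_norm, alpha_raw)
    alpha = np.exp(
        (1 - TREND_SHRINKAGE) * np.log(alpha_raw) + TREND_SHRINKAGE * np.log(trend)
    )
    # genes whose raw estimate sits at the floor carry no overdispersion
    # evidence; keep them at the floor rather than pulling them up to the trend
    alpha = np.where(alpha_raw <= DISPERSION_FLOOR, DISPERSION_FLOOR, alpha)
    return pd.Series(np.maximum(alpha, DISPERSION_FLOOR), index=counts.genes, name="dispersion")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise PipelineError("p must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PipelineError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def nb_wald_test(
    counts: CountMatrix,
    sf: pd.Series,
    disp: pd.Series,
    labels: pd.Series,
) -> pd.DataFrame:
    """Two-group NB Wald test; log2FC is group 1 over group 0.

    Per gene: group means of normalized counts, delta-method standard error
    of the log2 fold change from the NB variance mu/sf + alpha mu^2, Wald
    statistic and two-sided normal p, BH-adjusted q. Genes with zero counts
    in both groups get log2FC 0, p 1 and are flagged in ``zero_gene``.
    """
    samples = labels.index
    y = labels.to_numpy()
    if len(np.unique(y)) != 2:
        raise PipelineError("labels must contain both classes")
    s = sf.loc[samples].to_numpy()
    X = counts.counts[samples].to_numpy(dtype=float)
    Xn = X / s
    alpha = disp.loc[counts.genes].to_numpy()

    out = {}
    mus, vars_ = {}, {}
    for g in (0, 1):
        cols = y == g
        sub = Xn[:, cols]
        n = cols.sum()
        mu = sub.mean(axis=1)
        # Var(K_i / s_i) = mu / s_i + alpha mu^2 under NB with mean s_i mu
        var_hat = (mu[:, None] / s[None, cols] + alpha[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        mus[g], vars_[g] = mu, var_hat
    zero = (mus[0] <= 0) & (mus[1] <= 0)
    eps = 1e-12
    m0 = np.maximum(mus[0], eps)
    m1 = np.maximum(mus[1], eps)
    log2fc = np.log2(m1 / m0)
    se = np.sqrt(vars_[1] / m1**2 + vars_[0] / m0**2) / np.log(2)
    se = np.maximum(se, eps)
    wald = log2fc / se
    p = 2 * stats.norm.sf(np.abs(wald))
    log2fc[zero] = 0.0
    wald[zero] = 0.0
    p[zero] = 1.0
    out = pd.DataFrame(
        {
            "baseMean": Xn.mean(axis=1),
            "log2FC": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "q": bh_adjust(p),
            "zero_gene": zero,
        },
        index=counts.genes,
    )
    return out


def run_de(
    counts: CountMatrix, ann: SampleAnnotation, samples=None
) -> pd.DataFrame:
    """Full-data DE of any-bacterial vs nonbacterial on the ARI samples."""
    labels = ann.binary_labels(samples)
    cm = counts.subset(samples=labels.index)
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf, labels)
    return nb_wald_test(cm, sf, disp, labels)


def lobo_de_consistency(
    counts: CountMatrix, ann: SampleAnnotation, fdr: float = 0.05
) -> tuple[list[str], float]:
    """Leave-one-batch-out consistency of the significant gene set.

    Runs full-data DE, then repeats it leaving out each batch in turn; the
    core set is the full-data significant genes that stay significant in
    every leave-one-batch-out run, and the consistency fraction is
    |core| / |full-data significant| (NaN when nothing is significant).
    """
    ari = ann.ari_samples()
    batches = ann.batch.loc[ari]
    if batches.nunique() < 2:
        raise PipelineError("need at least 2 batches for LOBO consistency")
    full = run_de(counts, ann)
    sig = set(full.index[full["q"] < fdr])
    if not sig:
        return [], float("nan")
    core = set(sig)
    for b in sorted(batches.unique()):
        keep = ari[(batches != b).to_numpy()]
        labels = ann.binary_labels(keep)
        if labels.nunique() < 2:
            warnings.warn(f"leaving out batch {b!r} empties one class; fold skipped")
            continue
        res = run_de(counts, ann, samples=keep)
        core &= set(res.index[res["q"] < fdr])
    return sorted(core), len(core) / len(sig)
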