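"""QC cascade: CPM normalization, low-expression gene filtering, PCA sample
outlier removal, and batch-variance gene filtering.

The cascade order is: mean-CPM gene filter -> PCA outlier sample removal ->
CPM recomputed on retained samples -> batch-variance gene filter. CPM is
recomputed after sample removal because library composition changes; the
downstream statistics should not depend on samples that were discarded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import (
    CountMatrix,
    ExpressionMatrix,
    FilterReport,
    PipelineError,
    SampleAnnotation,
)

LOG_PSEUDOCOUNT = 1.0  # log transform is log2(CPM + 1); zero-safe
_MAD_SCALE = 1.4826  # MAD -> SD under normality


def compute_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / library size x 1e6; columns sum to 1e6."""
    lib = counts.libsize
    zero = lib.index[lib == 0]
    if len(zero):
        raise PipelineError(f"zero library size for sample(s): {list(zero[:5])}")
    cpm = counts.counts / lib * 1e6
    return ExpressionMatrix(cpm, "cpm")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1)."""
    expr.require_scale("cpm")
    return ExpressionMatrix(np.log2(expr.values + LOG_PSEUDOCOUNT), "log2cpm")


def filter_genes_by_mean_cpm(expr: ExpressionMatrix, threshold: float = 2.0) -> pd.Series:
    """Boolean keep-mask per gene: retained iff mean CPM >= threshold.

    The boundary is kept: the removal rule is strictly mean CPM < threshold.
    """
    expr.require_scale("cpm")
    if threshold < 0:
        raise PipelineError("threshold must be non-negative")
    return expr.values.mean(axis=1) >= threshold


def detect_outlier_samples_pca(
    expr: ExpressionMatrix,
    n_components: int = 2,
    sd_multiplier: float = 6.0,
) -> pd.Series:
    """Flag samples extreme on leading principal components.

    PCA is run on gene-centered log2-CPM; a sample is an outlier iff any of
    its first ``n_components`` scores lies more than ``sd_multiplier``
    robust SDs (1.4826 x MAD) from the component median. Deterministic.
    Returns a boolean Series, True = outlier.
    """
    expr.require_scale("log2cpm")
    n_samples = expr.values.shape[1]
    if n_samples < 3:
        raise PipelineError("need at least 3 samples for PCA outlier detection")
    max_comp = min(expr.values.shape[0], n_samples - 1)
    if n_components > max_comp:
        raise PipelineError(
            f"n_components={n_components} exceeds min(genes, samples-1)={max_comp}"
        )
    X = expr.values.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * _MAD_SCALE
    mad = np.where(mad > 0, mad, np.finfo(float).eps)
    flag = (np.abs(scores - med) > sd_multiplier * mad).any(axis=1)
    return pd.Series(flag, index=expr.samples)


@dataclass(frozen=True)
class BatchVarRule:
    """Remove genes whose between-batch variance fraction exceeds the cap."""

    max_batch_fraction: float = 0.5


def batch_variance_components(
    expr: ExpressionMatrix, batches: pd.Series
) -> pd.DataFrame:
    """Per-gene between/within batch variance components (one-way layout).

    Method-of-moments on the one-way ANOVA mean squares:
    sigma2_within = MSW, sigma2_between = max(0, (MSB - MSW) / n0) with n0
    the effective per-batch sample size. Batches with fewer than 2 samples
    are excluded from the estimate with a warning.
    """
    expr.require_scale("log2cpm")
    batches = batches.loc[expr.samples]
    sizes = batches.value_counts()
    small = sizes.index[sizes < 2]
    if len(small):
        warnings.warn(
            f"batch(es) with < 2 samples excluded from variance estimate: {list(small)}"
        )
        keep = ~batches.isin(small)
        batches = batches[keep]
    X = expr.values[batches.index].to_numpy()
    groups = [np.flatnonzero((batches == b).to_numpy()) for b in sizes.index if sizes[b] >= 2]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    zeros = np.zeros(X.shape[0])
    if k < 2:
        warnings.warn("fewer than 2 usable batches; between-batch variance set to 0")
        within = X.var(axis=1, ddof=1) if X.shape[1] > 1 else zeros
        return pd.DataFrame(
            {"between": zeros, "within": within}, index=expr.genes
        )
    grand = X.mean(axis=1, keepdims=True)
    ssb = zeros.copy()
    ssw = zeros.copy()
    for g in groups:
        sub = X[:, g]
        m = sub.mean(axis=1, keepdims=True)
        ssb += len(g) * (m - grand)[:, 0] ** 2
        ssw += ((sub - m) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    n0 = (n_total - sum(len(g) ** 2 for g in groups) / n_total) / (k - 1)
    between = np.maximum(0.0, (msb - msw) / n0)
    return pd.DataFrame({"between": between, "within": msw}, index=expr.genes)


def filter_genes_by_batch_variance(
    expr: ExpressionMatrix,
    batches: pd.Series,
    rule: BatchVarRule = BatchVarRule(),
) -> pd.Series:
    """Keep-mask: gene retained iff between/(between+within) <= cap.

    Genes with zero total variance are retained (no batch structure).
    """
    comp = batch_variance_components(expr, batches)
    total = comp["between"] + comp["within"]
    frac = np.where(total > 0, comp["between"] / np.where(total > 0, total, 1.0), 0.0)
    return pd.Series(frac <= rule.max_batch_fraction, index=expr.genes)


@dataclass
class PreprocessResult:
    counts: CountMatrix  # retained genes x retained samples
    cpm: ExpressionMatrix  # recomputed on retained samples
    log2cpm: ExpressionMatrix
    annotation: SampleAnnotation
    report: FilterReport


def run_preprocess(
    counts: CountMatrix,
    ann: SampleAnnotation,
    *,
    min_mean_cpm: float = 2.0,
    pca_components: int = 2,
    pca_sd_multiplier: float = 6.0,
    batch_var_rule: BatchVarRule = BatchVarRule(),
) -> PreprocessResult:
    """The full QC cascade with a reconciled :class:`FilterReport`."""
    report = FilterReport(n_genes_in=counts.n_genes, n_samples_in=counts.n_samples)

    cpm0 = compute_cpm(counts)
    keep_expr = filter_genes_by_mean_cpm(cpm0, min_mean_cpm)
    report.genes_removed_mean_cpm = list(counts.genes[~keep_expr])
    cm = counts.subset(genes=counts.genes[keep_expr])

    log0 = log_transform(compute_cpm(cm))
    outlier = detect_outlier_samples_pca(log0, pca_components, pca_sd_multiplier)
    report.samples_removed_pca = list(counts.samples[outlier.reindex(counts.samples, fill_value=False)])
    keep_samples = cm.samples[~outlier]
    cm = cm.subset(samples=keep_samples)

    cpm = compute_cpm(cm)  # recompute: library composition changed
    log2cpm = log_transform(cpm)
    ann_kept = ann.subset(keep_samples)
    keep_bv = filter_genes_by_batch_variance(log2cpm, ann_kept.batch, batch_var_rule)
    report.genes_removed_batch_variance = list(cm.genes[~keep_bv])
    cm = cm.subset(genes=cm.genes[keep_bv])

    cpm = ExpressionMatrix(cpm.values.loc[cm.genes], "cpm")
    log2cpm = ExpressionMatrix(log2cpm.values.loc[cm.genes], "log2cpm")

    report.genes_retained = list(cm.genes)
    report.samples_retained = list(cm.samples)
    report.validate()
    return PreprocessResult(cm, cpm, log2cpm, ann_kept, report)
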