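"""Synthetic whole-blood RNA-seq cohorts with a planted sparse signature.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of viral (V), bacterial (B), mixed (VB) and non-infected
(NI) samples sequenced in several batches, negative-binomial counts with a
gene-specific mean--dispersion trend, unequal library sizes, batch-level
mean shifts, a broad background of weak host-response differential
expression, and a small planted signature (by default three genes elevated
in bacterial infection and one interferon-like gene elevated in viral
infection).

Counts for gene g in sample s are drawn as a gamma-Poisson mixture with

    E[K_gs] = L_s * 2^(b_g + delta_g(class_s) + u_{batch_s, g}) / 1e6
    Var[K_gs] = mu + alpha_g * mu^2

where ``b_g`` is a baseline log2-CPM, ``delta_g`` the class effect in log2
units, ``u`` a batch mean shift and ``L_s`` the expected library size.
Mixed (VB) samples carry the full bacterial-direction effects plus the
viral-direction effect attenuated by a mixing factor.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, PipelineError, SampleAnnotation

UP_IN_BACTERIAL = "up-in-bacterial"
UP_IN_VIRAL = "up-in-viral"

_DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class SignatureGeneSpec:
    """One planted signature gene: position, direction and log2 effect size."""

    gene_index: int
    direction: str  # UP_IN_BACTERIAL | UP_IN_VIRAL
    effect: float  # log2 units, > 0


def _default_signature() -> tuple[SignatureGeneSpec, ...]:
    # three bacterial-elevated genes and one interferon-like viral-elevated
    # gene, mirroring the ITGB4/ITGA7/FAM20A-up, IFI27-down pattern of the
    # bacterial host response
    return (
        SignatureGeneSpec(11, UP_IN_BACTERIAL, 1.8),
        SignatureGeneSpec(57, UP_IN_BACTERIAL, 1.6),
        SignatureGeneSpec(131, UP_IN_BACTERIAL, 1.5),
        SignatureGeneSpec(211, UP_IN_VIRAL, 2.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the structure of the study cohort: 280 viral,
    129 bacterial and 95 mixed samples plus 64 non-infected controls,
    sequenced in 7 batches, with ~8,000 expressed genes of which roughly
    70% show some (mostly weak) host-response differential expression.
    """

    n_genes: int = 8000
    n_viral: int = 280
    n_bacterial: int = 129
    n_mixed: int = 95
    n_controls: int = 64
    n_batches: int = 7
    signature: tuple[SignatureGeneSpec, ...] = field(default_factory=_default_signature)
    vb_viral_attenuation: float = 0.5  # fraction of viral effect carried by VB
    batch_effect_sd: float = 0.25  # log2 sd of per-(batch, gene) mean shifts
    baseline_log2cpm_mean: float = 5.0
    baseline_log2cpm_sd: float = 2.0
    dispersion_asymptote: float = 0.08  # alpha at high expression
    dispersion_slope: float = 3.0  # alpha(mu) = asymptote + slope / mu
    dispersion_lognorm_sd: float = 0.25  # gene-level scatter around the trend
    libsize_min: float = 4e6
    libsize_max: float = 2e7
    fraction_null_genes: float = 0.30
    n_weak_de_genes: int | None = None  # default: the non-null, non-signature rest
    weak_effect_sd: float = 0.15  # log2 sd of weak background effects
    weak_effect_max: float = 0.4  # |weak effect| cap: signature genes are the extreme tail
    n_outlier_samples: int = 0
    outlier_gene_sd: float = 3.0  # log2 sd of per-gene shifts in outlier samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_batches <= 0:
            raise PipelineError("n_genes and n_batches must be positive")
        for n in (self.n_viral, self.n_bacterial, self.n_mixed, self.n_controls):
            if n < 0:
                raise PipelineError("class sizes must be non-negative")
        if self.n_viral + self.n_bacterial + self.n_mixed <= 0:
            raise PipelineError("need at least one ARI sample")
        idx = [g.gene_index for g in self.signature]
        if len(set(idx)) != len(idx):
            raise PipelineError("signature gene indices must be distinct")
        if any(i < 0 or i >= self.n_genes for i in idx):
            raise PipelineError("signature gene index out of range")
        for g in self.signature:
            if g.direction not in (UP_IN_BACTERIAL, UP_IN_VIRAL):
                raise PipelineError(f"unknown signature direction {g.direction!r}")
            if not np.isfinite(g.effect):
                raise PipelineError("signature effect sizes must be finite")
        if self.libsize_min <= 0 or self.libsize_min > self.libsize_max:
            raise PipelineError("library size range invalid")
        if self.dispersion_asymptote <= 0 or self.dispersion_slope < 0:
            raise PipelineError("dispersion trend parameters must be positive")
        if not 0 <= self.fraction_null_genes <= 1:
            raise PipelineError("fraction_null_genes must lie in [0, 1]")

    def scaled_down(self, n_genes: int = 2000, n_samples: int = 250,
                    n_controls: int = 0, seed: int | None = None) -> "SimConfig":
        """A smaller cohort with the same class proportions and structure.

        Used for simulation studies where many replicate cohorts are fit;
        the 280:129:95 class ratio and the 7-batch layout are preserved.
        """
        total = self.n_viral + self.n_bacterial + self.n_mixed
        n_v = int(round(n_samples * self.n_viral / total))
        n_b = int(round(n_samples * self.n_bacterial / total))
        n_vb = n_samples - n_v - n_b
        return replace(
            self,
            n_genes=n_genes,
            n_viral=n_v,
            n_bacterial=n_b,
            n_mixed=n_vb,
            n_controls=n_controls,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``class_offsets`` holds the per-gene log2 mean offset of every outcome
    class relative to baseline; ``bacterial_contrast`` is the log2 effect of
    the pooled any-bacterial vs nonbacterial comparison implied by those
    offsets (B and VB averaged with their class sizes). ``oracle_scores``
    is the linear discriminant on the planted signature genes — the score an
    observer who knows the generative effects would use — and its AUC is the
    reference the fitted pipeline is compared against.
    """

    signature: tuple[SignatureGeneSpec, ...]
    signature_genes: list[str]
    class_offsets: pd.DataFrame  # genes x classes (V, B, VB, NI), log2 units
    de_genes: list[str]  # genes with a nonzero any-bacterial contrast
    bacterial_contrast: pd.Series  # per-gene log2 effect, B/VB pooled vs V
    sample_class: pd.Series
    oracle_scores: pd.Series
    dispersions: pd.Series | None = None  # per-gene NB alpha actually used
    outlier_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.signature_genes) <= set(self.de_genes):
            raise PipelineError("signature genes must be differentially expressed")

    def theoretical_auc(self) -> float:
        """AUC of the planted oracle score for any-bacterial vs nonbacterial."""
        from .evaluate import roc_auc

        cls = self.sample_class
        mask = cls != "NI"
        y = cls[mask].isin(("B", "VB")).astype(int).to_numpy()
        return roc_auc(self.oracle_scores[mask].to_numpy(), y)[1]


def _class_offsets(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene log2 offsets for classes (V, B, VB, NI), genes x 4."""
    off = np.zeros((cfg.n_genes, 4))  # columns V, B, VB, NI
    sig_idx = {g.gene_index for g in cfg.signature}
    n_nonnull = int(round((1 - cfg.fraction_null_genes) * cfg.n_genes))
    n_weak = cfg.n_weak_de_genes
    if n_weak is None:
        n_weak = max(0, n_nonnull - len(cfg.signature))
    candidates = np.array([i for i in range(cfg.n_genes) if i not in sig_idx])
    weak = rng.choice(candidates, size=min(n_weak, len(candidates)), replace=False)
    # weak background host-response effects on the bacterial-vs-viral axis,
    # carried equally by B and VB; truncated so the planted signature genes
    # sit in the extreme tail of the effect-size distribution
    eff = np.clip(
        rng.normal(0.0, cfg.weak_effect_sd, size=len(weak)),
        -cfg.weak_effect_max,
        cfg.weak_effect_max,
    )
    off[weak, 1] += eff
    off[weak, 2] += eff
    for g in cfg.signature:
        if g.direction == UP_IN_BACTERIAL:
            off[g.gene_index, 1] += g.effect
            off[g.gene_index, 2] += g.effect
        else:  # elevated in viral infection; VB carries an attenuated copy
            off[g.gene_index, 0] += g.effect
            off[g.gene_index, 2] += cfg.vb_viral_attenuation * g.effect
    return off


def _draw_counts(mu: np.ndarray, alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha * mu^2 (alpha per gene)."""
    shape = 1.0 / np.maximum(alpha, _DISPERSION_FLOOR)[:, None]
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def generate_cohort(cfg: SimConfig) -> tuple[CountMatrix, SampleAnnotation, SimTruth]:
    """Simulate a training cohort; reproducible given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    classes = (
        ["V"] * cfg.n_viral + ["B"] * cfg.n_bacterial
        + ["VB"] * cfg.n_mixed + ["NI"] * cfg.n_controls
    )
    n_samples = len(classes)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    cls = pd.Series(pd.Categorical(classes), index=samples).astype(str)
    cls.index.name = "sample_id"

    # batch assignment: shuffle then split evenly, so every batch mixes classes
    order = rng.permutation(n_samples)
    batch = np.empty(n_samples, dtype=object)
    for b, chunk in enumerate(np.array_split(order, cfg.n_batches)):
        batch[chunk] = f"batch{b + 1}"

    baseline = rng.normal(cfg.baseline_log2cpm_mean, cfg.baseline_log2cpm_sd, cfg.n_genes)
    offsets = _class_offsets(cfg, rng)
    batch_shift = rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_batches, cfg.n_genes))
    libsize = np.exp(rng.uniform(np.log(cfg.libsize_min), np.log(cfg.libsize_max), n_samples))

    class_col = {"V": 0, "B": 1, "VB": 2, "NI": 3}
    cls_idx = np.array([class_col[c] for c in classes])
    batch_idx = np.array([int(b[5:]) - 1 for b in batch])

    log2mu = (
        baseline[:, None]
        + offsets[:, cls_idx]
        + batch_shift[batch_idx, :].T
    )

    outliers: list[str] = []
    if cfg.n_outlier_samples > 0:
        out_pos = rng.choice(n_samples, size=cfg.n_outlier_samples, replace=False)
        outliers = [samples[i] for i in sorted(out_pos)]
        # heterogeneous per-gene shifts: survive CPM normalization, unlike a
        # uniform shift which only rescales the library
        log2mu[:, out_pos] += rng.normal(
            0.0, cfg.outlier_gene_sd, size=(cfg.n_genes, len(out_pos))
        )

    mu = libsize[None, :] * np.exp2(log2mu) / 1e6
    mean_expr = mu.mean(axis=1)
    alpha = (
        cfg.dispersion_asymptote + cfg.dispersion_slope / np.maximum(mean_expr, 1e-8)
    ) * np.exp(rng.normal(0.0, cfg.dispersion_lognorm_sd, cfg.n_genes))

    counts = _draw_counts(mu, alpha, rng)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    ann = SampleAnnotation(
        pd.DataFrame({"batch": batch, "class": classes}, index=pd.Index(samples, name="sample_id"))
    )

    contrast = _bacterial_contrast(offsets, cfg)
    de_mask = contrast != 0
    weights = _oracle_weights(cfg)
    # oracle score: planted-effect-weighted log2 CPM of the signature genes
    cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
    sig_rows = [g.gene_index for g in cfg.signature]
    scores = weights @ np.log2(cpm[sig_rows, :] + 1.0)

    truth = SimTruth(
        signature=cfg.signature,
        signature_genes=[genes[g.gene_index] for g in cfg.signature],
        class_offsets=pd.DataFrame(offsets, index=genes, columns=["V", "B", "VB", "NI"]),
        de_genes=[genes[i] for i in np.flatnonzero(de_mask)],
        bacterial_contrast=pd.Series(contrast, index=genes),
        sample_class=cls,
        oracle_scores=pd.Series(scores, index=samples),
        dispersions=pd.Series(alpha, index=genes),
        outlier_samples=outliers,
    )
    return cm, ann, truth


def _bacterial_contrast(offsets: np.ndarray, cfg: SimConfig) -> np.ndarray:
    n_bact = cfg.n_bacterial + cfg.n_mixed
    if n_bact == 0:
        return np.zeros(offsets.shape[0])
    pooled = (cfg.n_bacterial * offsets[:, 1] + cfg.n_mixed * offsets[:, 2]) / n_bact
    return pooled - offsets[:, 0]


def _oracle_weights(cfg: SimConfig) -> np.ndarray:
    return np.array(
        [g.effect if g.direction == UP_IN_BACTERIAL else -g.effect for g in cfg.signature]
    )


def generate_validation_cohort(
    truth: SimTruth,
    cfg: SimConfig,
    *,
    seed: int | None = None,
    effect_scale: float = 1.0,
    libsize_scale: float = 1.0,
    n_batches: int = 2,
    n_viral: int | None = None,
    n_bacterial: int | None = None,
    n_mixed: int | None = None,
) -> tuple[CountMatrix, SampleAnnotation]:
    """An independently processed external cohort sharing the planted biology.

    Keeps the class effects of ``truth`` (optionally rescaled by
    ``effect_scale``) but redraws baselines, dispersions, batches and library
    sizes, emulating a validation dataset generated by a different lab and
    pipeline. ``libsize_scale`` applies a global sequencing-depth rescaling.
    """
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    n_genes = truth.class_offsets.shape[0]
    genes = list(truth.class_offsets.index)
    n_v = cfg.n_viral if n_viral is None else n_viral
    n_b = cfg.n_bacterial if n_bacterial is None else n_bacterial
    n_vb = cfg.n_mixed if n_mixed is None else n_mixed
    classes = ["V"] * n_v + ["B"] * n_b + ["VB"] * n_vb
    n_samples = len(classes)
    if n_samples == 0:
        raise PipelineError("validation cohort must contain samples")
    samples = [f"X{i:04d}" for i in range(n_samples)]

    order = rng.permutation(n_samples)
    batch = np.empty(n_samples, dtype=object)
    for b, chunk in enumerate(np.array_split(order, n_batches)):
        batch[chunk] = f"vbatch{b + 1}"

    baseline = rng.normal(cfg.baseline_log2cpm_mean, cfg.baseline_log2cpm_sd, n_genes)
    offsets = truth.class_offsets.to_numpy() * effect_scale
    batch_shift = rng.normal(0.0, cfg.batch_effect_sd, size=(n_batches, n_genes))
    libsize = libsize_scale * np.exp(
        rng.uniform(np.log(cfg.libsize_min), np.log(cfg.libsize_max), n_samples)
    )

    class_col = {"V": 0, "B": 1, "VB": 2, "NI": 3}
    cls_idx = np.array([class_col[c] for c in classes])
    batch_idx = np.array([int(b[6:]) - 1 for b in batch])
    log2mu = baseline[:, None] + offsets[:, cls_idx] + batch_shift[batch_idx, :].T
    mu = libsize[None, :] * np.exp2(log2mu) / 1e6
    mean_expr = mu.mean(axis=1)
    alpha = (
        cfg.dispersion_asymptote + cfg.dispersion_slope / np.maximum(mean_expr, 1e-8)
    ) * np.exp(rng.normal(0.0, cfg.dispersion_lognorm_sd, n_genes))
    counts = _draw_counts(mu, alpha, rng)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    ann = SampleAnnotation(
        pd.DataFrame({"batch": batch, "class": classes}, index=pd.Index(samples, name="sample_id"))
    )
    return cm, ann
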