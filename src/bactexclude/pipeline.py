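"""End-to-end orchestration: simulate -> preprocess -> DE -> CV -> final
signature -> threshold -> external validation, driven by one YAML-able
configuration and a single seed, with a run manifest for reproducibility.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, diffexp, evaluate, io, preprocess, signature, simulate
from .datatypes import CountMatrix, PipelineError, SampleAnnotation


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    counts_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    min_mean_cpm: float = 2.0
    pca_components: int = 2
    pca_sd_multiplier: float = 6.0
    max_batch_fraction: float = 0.5
    de_fdr: float = 0.05
    run_lobo_consistency: bool = True
    grid: dict = field(default_factory=dict)  # overrides for TuningGrid
    sparsity_budget: int | None = 6
    target_sensitivity: float = 0.90
    prevalence_grid: tuple[float, ...] = evaluate.DEFAULT_PREVALENCE_GRID
    refit_external_transform: bool = False
    run_nested_cv: bool = True
    run_validation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_sensitivity <= 1:
            raise PipelineError("target sensitivity must lie in (0, 1]")
        if self.de_fdr <= 0 or self.de_fdr >= 1:
            raise PipelineError("de_fdr must lie in (0, 1)")
        if not self.simulate:
            for p in (self.counts_path, self.annotation_path):
                if p is None:
                    raise PipelineError("counts_path and annotation_path required")
                if not Path(p).exists():
                    raise PipelineError(f"input path does not exist: {p}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["prevalence_grid"] = [float(x) for x in self.prevalence_grid]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "prevalence_grid" in d:
            d["prevalence_grid"] = tuple(d["prevalence_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(seed=self.seed, **self.sim)

    def tuning_grid(self) -> signature.TuningGrid:
        d = dict(self.grid)
        for key in ("gammas", "taus", "lambdas"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return signature.TuningGrid(**d)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; optionally write every artifact to disk.

    Returns a bundle with the preprocessing report, DE table, CV result,
    final model, threshold report and (when simulating) external
    validation, plus a manifest of stage timings, versions and the config
    hash sufficient to re-execute the run.
    """
    timings: dict[str, float] = {}
    bundle: dict = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _T()

    truth = None
    with stage("input"):
        if config.simulate:
            cm, ann, truth = simulate.generate_cohort(config.sim_config())
        else:
            cm = io.read_counts(config.counts_path)
            ann = io.read_annotation(config.annotation_path)
            ann = SampleAnnotation(ann.table.loc[cm.samples])

    with stage("preprocess"):
        prep = preprocess.run_preprocess(
            cm,
            ann,
            min_mean_cpm=config.min_mean_cpm,
            pca_components=config.pca_components,
            pca_sd_multiplier=config.pca_sd_multiplier,
            batch_var_rule=preprocess.BatchVarRule(config.max_batch_fraction),
        )
    bundle["filter_report"] = prep.report

    with stage("diffexp"):
        de = diffexp.run_de(prep.counts, prep.annotation)
        bundle["de"] = de
        bundle["n_de_genes"] = int((de["q"] < config.de_fdr).sum())
        if config.run_lobo_consistency:
            core, frac = diffexp.lobo_de_consistency(
                prep.counts, prep.annotation, config.de_fdr
            )
            bundle["lobo_core_genes"] = core
            bundle["lobo_consistency_fraction"] = frac

    # modeling uses the ARI samples only
    labels = prep.annotation.binary_labels()
    ari = labels.index
    expr_cpm_ari = type(prep.cpm)(prep.cpm.values[ari], "cpm")
    X_log = np.log2(prep.cpm.values[ari].to_numpy().T + preprocess.LOG_PSEUDOCOUNT)
    y = labels.to_numpy()
    batches = prep.annotation.batch.loc[ari].to_numpy()
    grid = config.tuning_grid()

    if config.run_nested_cv:
        with stage("nested_cv"):
            cv = signature.nested_lobo_cv(X_log, y, batches, grid, config.sparsity_budget)
            bundle["cv"] = cv

    with stage("final_fit"):
        model = signature.fit_final_signature(
            X_log, y, batches, grid, config.sparsity_budget, gene_names=list(prep.counts.genes)
        )
        bundle["model"] = model

    with stage("threshold"):
        scores = evaluate.risk_score(model, expr_cpm_ari)
        bundle["training_scores"] = scores
        bundle["training_auc"] = evaluate.roc_auc(scores.to_numpy(), y)[1]
        report = evaluate.threshold_for_sensitivity(
            scores.to_numpy(), y, config.target_sensitivity, config.prevalence_grid
        )
        bundle["threshold_report"] = report
        ni = prep.annotation.table.index[prep.annotation.table["class"] == "NI"]
        if len(ni):
            ni_expr = type(prep.cpm)(prep.cpm.values[ni], "cpm")
            ni_scores = evaluate.risk_score(model, ni_expr)
            bundle["ni_classification"] = evaluate.classify(
                ni_scores.to_numpy(), None, report.threshold
            )

    if config.run_validation and truth is not None:
        with stage("validation"):
            vcm, vann = simulate.generate_validation_cohort(
                truth, config.sim_config(), seed=config.seed + 104729
            )
            vexpr = preprocess.compute_cpm(vcm)
            vy = vann.binary_labels().to_numpy()
            bundle["validation"] = evaluate.evaluate_external(
                model, vexpr, vy, refit_transform=config.refit_external_transform
            )

    if truth is not None:
        bundle["truth"] = truth
        bundle["theoretical_auc"] = truth.theoretical_auc()

    bundle["manifest"] = {
        "pipeline_version": __version__,
        "config_hash": config.config_hash(),
        "config_yaml": config.to_yaml(),
        "seed": config.seed,
        "timings_s": timings,
    }

    if out_dir is not None:
        _write_bundle(bundle, config, prep, Path(out_dir))
    return bundle


def _write_bundle(bundle, config, prep, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_counts_tsv(prep.counts, out / "filtered_counts.tsv")
    io.write_annotation(prep.annotation, out / "filtered_annotation.csv")
    io.write_json(bundle["filter_report"].to_dict(), out / "filter_report.json")
    bundle["de"].to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id")
    (out / "model.json").write_text(bundle["model"].to_json() + "\n")
    io.write_json(bundle["threshold_report"].to_dict(), out / "threshold_report.json")
    bundle["training_scores"].rename_axis("sample_id").to_frame().to_csv(
        out / "training_scores.tsv", sep="\t"
    )
    if "cv" in bundle:
        cv = bundle["cv"]
        io.write_json(
            {
                "pooled_auc": cv.pooled_auc,
                "per_fold_auc": cv.per_fold_auc,
                "folds": [
                    {"batch": str(f.batch), "tuning": f.tuning, "n_held_out": len(f.scores)}
                    for f in cv.folds
                ],
            },
            out / "cv_report.json",
        )
    if "validation" in bundle:
        v = bundle["validation"]
        io.write_json(
            {k: v[k] for k in ("auc", "auc_carried_transform", "auc_refit_transform", "transform_mode")},
            out / "validation_report.json",
        )
    io.write_json(bundle["manifest"], out / "manifest.json")
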