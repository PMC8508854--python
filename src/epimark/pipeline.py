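"""End-to-end orchestration: simulate/load -> preprocess -> select ->
validate -> biomarker, with reproducible machine-readable outputs.

A run is fully described by a :class:`RunConfig` (either input paths or a
generator config, never both) and is deterministic given its seed: two
runs with the same config produce byte-identical ``report.json`` files
(timestamps live in a separate metadata file).  When the inputs come from
the simulator, recovery metrics against the planted truth (sensitivity and
false-discovery rate of the validated set, biomarker recall over the
planted predictive set) are part of the report.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .biomarker import BiomarkerModel, StepwiseLogisticRegression
from .preprocess import beta_to_m, bmiq_normalize, filter_probes
from .select import DoublePCASelector, SelectionParams, SelectionResult
from .simulate import GeneratorConfig, SimulatedDataset, TruthSet, generate_dataset
from .site_stats import (SiteTestResult, gene_summary, group_descriptives,
                         test_sites, validate_sites)

__all__ = ["InputPaths", "RunConfig", "ReportBundle", "run_pipeline",
           "compute_recovery"]

log = logging.getLogger("epimark")


@dataclass(frozen=True)
class InputPaths:
    manifest: str
    sample_sheet: str
    beta_baseline: str
    beta_followup: str
    detp_baseline: str
    detp_followup: str


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``inputs`` / ``generator`` must be set.  The biomarker
    stage defaults to a ridge penalty of 1.0 because the design is
    deliberately p-greater-than-n (tens of validated candidate CpGs
    against 2 x 9 subjects), where the unpenalized likelihood separates
    by construction.
    """

    generator: GeneratorConfig | None = None
    inputs: InputPaths | None = None
    selection: SelectionParams = field(default_factory=SelectionParams)
    p_cut: float = 0.01
    frac_cut: float = 0.10
    skip_bmiq: bool = False
    alpha: float = 0.05
    require_concordance: bool = True
    alpha_stay: float = 0.05
    stepwise_criterion: str = "wald_p"
    penalty: float = 1.0
    covariates: tuple[str, ...] = ("triglycerides",)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if (self.generator is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of generator config or input paths is required")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()}
        # the report must be byte-identical across output locations
        d["outdir"] = None
        return d


@dataclass
class ReportBundle:
    config: RunConfig
    filter_report: object
    selection: SelectionResult
    site_tests: list[SiteTestResult]
    validated: list[SiteTestResult]
    gene_summaries: list
    descriptives: pd.DataFrame
    biomarker: BiomarkerModel | None
    recovery: dict | None
    stage_seconds: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "filter_report": self.filter_report.to_dict(),
            "selection": self.selection.to_dict(),
            "validated": [t.to_dict() for t in self.validated],
            "gene_summaries": [g.to_dict() for g in self.gene_summaries],
            "descriptives": self.descriptives.to_dict(orient="records"),
            "biomarker": self.biomarker.to_dict() if self.biomarker else None,
            "recovery": self.recovery,
        }


def compute_recovery(validated: list[SiteTestResult] | list[str],
                     model: BiomarkerModel | None,
                     truth: TruthSet) -> dict:
    """Sensitivity / FDR of the validated set against the planted
    differential CpGs, and biomarker recall over the planted predictive
    CpGs.  Empty validated sets give sensitivity 0 and FDR 0 (guarded
    denominator)."""
    ids = {t.probe_id if isinstance(t, SiteTestResult) else str(t)
           for t in validated}
    planted = truth.differential_cpgs
    tp = len(ids & planted)
    sensitivity = tp / len(planted) if planted else 0.0
    fdr = len(ids - planted) / max(1, len(ids))
    predictive = truth.predictive_cpgs
    final = set(model.predictors) if model is not None else set()
    recall = (len(final & predictive) / len(predictive)) if predictive else None
    return {
        "n_validated": len(ids),
        "n_planted_differential": len(planted),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "biomarker_recall": recall,
        "biomarker_hits": sorted(final & predictive),
    }


def _load_inputs(paths: InputPaths):
    manifest = eio.read_manifest(paths.manifest)
    sheet = eio.read_sample_sheet(paths.sample_sheet)
    return (manifest, sheet,
            eio.read_matrix(paths.beta_baseline),
            eio.read_matrix(paths.beta_followup),
            eio.read_matrix(paths.detp_baseline),
            eio.read_matrix(paths.detp_followup))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages in order, optionally writing every intermediate
    artifact below ``config.outdir``."""
    timings: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir else None

    def _tick(stage, t0):
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %-10s %.2fs", stage, timings[stage])

    t0 = time.perf_counter()
    truth: TruthSet | None = None
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        data = generate_dataset(gen)
        manifest, sheet, truth = data.manifest, data.sheet, data.truth
        bb, bf = data.beta_baseline, data.beta_followup
        db, df_ = data.detp_baseline, data.detp_followup
        if outdir:
            d = outdir / "simulate"
            d.mkdir(parents=True, exist_ok=True)
            eio.write_manifest(manifest, d / "manifest.tsv")
            eio.write_sample_sheet(sheet, d / "samples.csv")
            eio.write_json(truth.to_dict(), d / "truth.json")
    else:
        manifest, sheet, bb, bf, db, df_ = _load_inputs(config.inputs)
    _tick("inputs", t0)

    # --- preprocess: one filtering pass over all samples of both timepoints
    t0 = time.perf_counter()
    beta_all = pd.concat([bb, bf], axis=1)
    detp_all = pd.concat([db, df_], axis=1)
    beta_all, report = filter_probes(beta_all, detp_all, manifest,
                                     p_cut=config.p_cut,
                                     frac_cut=config.frac_cut)
    bb = beta_all[bb.columns]
    bf = beta_all[bf.columns]
    if not config.skip_bmiq:
        bb = bmiq_normalize(bb, manifest, seed=config.seed)
        bf = bmiq_normalize(bf, manifest, seed=config.seed)
    mb = beta_to_m(bb)
    mf = beta_to_m(bf)
    if outdir:
        d = outdir / "preprocess"
        d.mkdir(parents=True, exist_ok=True)
        eio.write_json(report.to_dict(), d / "filter_report.json")
        eio.write_matrix(bb, d / "beta_baseline_norm.tsv")
        eio.write_matrix(bf, d / "beta_followup_norm.tsv")
    _tick("preprocess", t0)

    # --- two-stage PCA selection
    t0 = time.perf_counter()
    sel = DoublePCASelector(stage1_fraction=config.selection.stage1_fraction,
                            n_components=config.selection.n_components,
                            combine=config.selection.combine)
    sel.fit(mf, mb)
    selection = sel.result_
    if outdir:
        d = outdir / "select"
        d.mkdir(parents=True, exist_ok=True)
        eio.write_json(selection.to_dict(), d / "selection.json")
        selection.stage2_contributions.to_csv(d / "stage2_contributions.tsv",
                                              sep="\t")
    _tick("select", t0)

    # --- per-site validation, gene summaries, descriptives
    t0 = time.perf_counter()
    groups = sheet["group"]
    validated = validate_sites(selection, bb, bf, mb, mf, groups,
                               alpha=config.alpha,
                               require_concordance=config.require_concordance)
    validated_genes = {manifest.loc[t.probe_id, "gene"] for t in validated
                       if t.probe_id in manifest.index}
    gene_probes = [pid for pid in manifest.index[
        manifest["gene"].isin(validated_genes - {""})] if pid in mb.index]
    all_tests = test_sites(gene_probes, bb, bf, mb, mf, groups)
    genes = gene_summary(validated, all_tests, manifest, alpha=config.alpha)
    descriptives = group_descriptives(sheet)
    if outdir:
        d = outdir / "validate"
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([t.to_dict() for t in validated]).to_csv(
            d / "validated_sites.tsv", sep="\t", index=False)
        pd.DataFrame([g.to_dict() for g in genes]).to_csv(
            d / "gene_summaries.tsv", sep="\t", index=False)
        descriptives.to_csv(d / "descriptives.tsv", sep="\t", index=False)
    _tick("validate", t0)

    # --- biomarker model on baseline M of validated sites
    t0 = time.perf_counter()
    model: BiomarkerModel | None = None
    if validated:
        base_samples = sheet[sheet["timepoint"] == "baseline"]
        X = mb.loc[[t.probe_id for t in validated], base_samples.index].T
        for cov in config.covariates:
            if cov in base_samples.columns:
                X[cov] = base_samples[cov].astype(float)
        y = (base_samples["group"] == "unstable_MHO").astype(int).to_numpy()
        est = StepwiseLogisticRegression(
            alpha_stay=config.alpha_stay, criterion=config.stepwise_criterion,
            penalty=config.penalty,
            covariates=[c for c in config.covariates if c in X.columns])
        est.fit(X, y)
        model = est.model_
        if outdir:
            d = outdir / "biomarker"
            d.mkdir(parents=True, exist_ok=True)
            eio.write_json(model.to_dict(), d / "model.json")
            model.to_frame().to_csv(d / "model.tsv", sep="\t")
    _tick("biomarker", t0)

    recovery = compute_recovery(validated, model, truth) if truth else None

    bundle = ReportBundle(config=config, filter_report=report,
                          selection=selection, site_tests=all_tests,
                          validated=validated, gene_summaries=genes,
                          descriptives=descriptives, biomarker=model,
                          recovery=recovery, stage_seconds=timings)
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        eio.write_json(bundle.to_dict(), outdir / "report.json")
        eio.write_json({"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                        "stage_seconds": timings,
                        "python": sys.version.split()[0]},
                       outdir / "run_metadata.json")
    return bundle
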