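"""Stage orchestration: simulate → baseline → gwas → expand → reduce →
select → evaluate, each stage a pure function of (inputs, config, seed),
with a manifest of input/output hashes for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .baseline_stats import baseline_table
from .config import StudyConfig
from .datatypes import CohortTable, GenotypeMatrix
from .evaluation import (evaluation_report, patient_breakdown,
                         reclassification_metrics)
from .gwas import genomic_lambda, logistic_snp_scan, qc_filter
from .network_expansion import build_candidate_set
from .redundancy import reduce_cohort
from .selection import outer_fold_models, run_two_phase_selection
from .synthetic_cohort import simulate_study

log = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "baseline", "gwas", "expand", "reduce",
               "select", "evaluate")

STAGE_REQUIRES = {
    "simulate": (),
    "baseline": ("phenotypes",),
    "gwas": ("genotypes", "phenotypes"),
    "expand": ("gwas_results", "annotation", "ppi", "genotypes_qc"),
    "reduce": ("phenotypes",),
    "select": ("reduced_phenotypes", "candidates", "genotypes_qc"),
    "evaluate": ("selection", "reduced_phenotypes", "genotypes_qc"),
}


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict) -> None:
        self.stages.append({
            "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {k: {"path": str(p), "sha256_16": _hash_file(p)}
                        for k, p in outputs.items()},
        })

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages},
            indent=2))


class PipelineState:
    """In-memory artifacts passed between stages."""

    def __init__(self, out_dir, config: StudyConfig):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.artifacts: dict = {}
        self.manifest = RunManifest(config=config.to_dict(),
                                    seed=config.rng_seed)

    def require(self, stage: str) -> None:
        missing = [a for a in STAGE_REQUIRES[stage]
                   if a not in self.artifacts]
        if missing:
            for prior, outs in PRODUCES.items():
                if set(missing) & set(outs):
                    raise RuntimeError(
                        f"stage {stage!r} requires {missing}; "
                        f"run {prior!r} first")
            raise RuntimeError(f"stage {stage!r} requires {missing}")


PRODUCES = {
    "simulate": ("genotypes", "phenotypes", "annotation", "ppi"),
    "gwas": ("genotypes_qc", "gwas_results"),
    "expand": ("candidates",),
    "reduce": ("reduced_phenotypes",),
    "select": ("selection",),
}


def stage_simulate(state: PipelineState, n_samples=457, n_snps=400,
                   **kwargs) -> None:
    gm, cohort, ann, ppi, spec = simulate_study(
        n_samples=n_samples, n_snps=n_snps, seed=state.config.rng_seed,
        **kwargs)
    state.artifacts.update(genotypes=gm, phenotypes=cohort,
                           annotation=ann, ppi=ppi, effect_spec=spec)
    paths = io_formats.write_study_inputs(gm, cohort, ann, ppi,
                                          state.out / "inputs")
    state.manifest.record("simulate", paths)


def stage_baseline(state: PipelineState) -> None:
    state.require("baseline")
    table = baseline_table(state.artifacts["phenotypes"])
    p = state.out / "baseline_table.tsv"
    table.to_csv(p, sep="\t", na_rep="NA")
    state.artifacts["baseline"] = table
    state.manifest.record("baseline", {"baseline_table": p})


def stage_gwas(state: PipelineState) -> None:
    state.require("gwas")
    gm, cohort, qc_report = qc_filter(state.artifacts["genotypes"],
                                      state.artifacts["phenotypes"],
                                      state.config)
    scan = logistic_snp_scan(gm, cohort)
    lam, qq = genomic_lambda(scan["p_wald"])
    state.artifacts.update(genotypes_qc=gm, phenotypes=cohort,
                           gwas_results=scan, genomic_lambda=lam)
    p_scan = state.out / "gwas_results.tsv"
    scan.to_csv(p_scan, sep="\t", na_rep="NA")
    p_qc = state.out / "qc_report.tsv"
    qc_report.to_csv(p_qc, sep="\t", index=False)
    p_qq = state.out / "qq_points.tsv"
    qq.assign(genomic_lambda=lam).to_csv(p_qq, sep="\t", index=False)
    state.manifest.record("gwas", {"gwas_results": p_scan,
                                   "qc_report": p_qc, "qq_points": p_qq})


def stage_expand(state: PipelineState) -> None:
    state.require("expand")
    cand = build_candidate_set(
        state.artifacts["gwas_results"], state.artifacts["annotation"],
        state.artifacts["ppi"], state.artifacts["genotypes_qc"],
        k=state.config.seed_k, r2_max=state.config.ld_r2_max,
        p_max=state.config.p_max)
    state.artifacts["candidates"] = cand
    p = state.out / "candidate_snps.tsv"
    cand.to_csv(p, sep="\t")
    state.manifest.record("expand", {"candidate_snps": p})


def stage_reduce(state: PipelineState) -> None:
    state.require("reduce")
    reduced, kept, trace = reduce_cohort(
        state.artifacts["phenotypes"],
        threshold=state.config.gower_threshold,
        tiebreak=state.config.hobohm_tiebreak)
    state.artifacts["reduced_phenotypes"] = reduced
    state.artifacts["removed_samples"] = trace
    p_kept = state.out / "kept_samples.tsv"
    pd.Series(kept, name="sample_id").to_csv(p_kept, sep="\t", index=False)
    p_rm = state.out / "removed_samples.tsv"
    pd.DataFrame(trace, columns=["sample_id", "degree_at_removal"]) \
        .to_csv(p_rm, sep="\t", index=False)
    state.manifest.record("reduce", {"kept_samples": p_kept,
                                     "removed_samples": p_rm})


CLINICAL_CANDIDATES = (
    "male_sex", "age", "weight", "bmi", "alcohol_use", "systolic_bp",
    "diastolic_bp", "pulse_pressure", "serum_glucose", "serum_insulin",
    "hba1c", "biguanides", "insulin_medication", "sulfonylureas",
    "insulin_sensitising_agents",
)


def stage_select(state: PipelineState) -> None:
    state.require("select")
    cohort = state.artifacts["reduced_phenotypes"]
    gm = state.artifacts["genotypes_qc"].subset(
        sample_ids=cohort.sample_ids)
    snp_candidates = state.artifacts["candidates"].index.tolist()
    clinical = [c for c in CLINICAL_CANDIDATES if c in cohort.covariates]
    result = run_two_phase_selection(cohort, gm, clinical, snp_candidates,
                                     state.config,
                                     seed=state.config.rng_seed)
    state.artifacts["selection"] = result
    p_clin = state.out / "clinical_feature_counts.tsv"
    result.clinical_table.to_csv(p_clin, sep="\t")
    p_snp = state.out / "snp_feature_counts.tsv"
    result.snp_table.to_csv(p_snp, sep="\t")
    records = pd.DataFrame(
        [{"outer": r.outer, "repeat": r.repeat, "inner": r.inner,
          "phase": ph, "selected": "|".join(r.selected),
          "auc_trajectory": "|".join(f"{a:.4f}" for a in r.auc_trajectory)}
         for ph, recs in (("clinical", result.clinical_records),
                          ("snp", result.snp_records))
         for r in recs])
    p_rec = state.out / "selection_records.tsv"
    records.to_csv(p_rec, sep="\t", index=False)
    state.manifest.record("select", {"clinical_feature_counts": p_clin,
                                     "snp_feature_counts": p_snp,
                                     "selection_records": p_rec})


def stage_evaluate(state: PipelineState) -> None:
    state.require("evaluate")
    from .ann import olden_importance

    cohort = state.artifacts["reduced_phenotypes"]
    gm = state.artifacts["genotypes_qc"].subset(sample_ids=cohort.sample_ids)
    sel = state.artifacts["selection"]
    clinical = sel.clinical_features
    snps = sel.snp_features
    plan = sel.plan

    models_c, scores_c, labels = outer_fold_models(cohort, gm, clinical,
                                                   plan, state.config)
    report = {"clinical": evaluation_report(scores_c, labels,
                                            state.config.score_cutoff)}
    importance = {"clinical": olden_importance(models_c)}
    if snps:
        models_f, scores_f, labels_f = outer_fold_models(
            cohort, gm, clinical + snps, plan, state.config)
        common = scores_c.index.intersection(scores_f.index)
        y = labels.loc[common]
        report["full"] = evaluation_report(scores_f.loc[common], y,
                                           state.config.score_cutoff)
        recl = reclassification_metrics(scores_c.loc[common],
                                        scores_f.loc[common], y,
                                        cutoffs=[state.config.score_cutoff])
        report["reclassification"] = {
            k: {"estimate": v.estimate, "z": v.z, "p_value": v.p_value}
            for k, v in recl.items()}
        counts, shift = patient_breakdown(scores_c.loc[common],
                                          scores_f.loc[common], y,
                                          state.config.score_cutoff)
        importance["full"] = olden_importance(models_f)
        p_groups = state.out / "patient_groups.tsv"
        counts.to_csv(p_groups, sep="\t")
        p_shift = state.out / "score_shift.tsv"
        shift.to_csv(p_shift, sep="\t", index=False)
    p_rep = state.out / "evaluation_report.json"
    p_rep.write_text(json.dumps(report, indent=2, default=float))
    p_imp = state.out / "importance.tsv"
    pd.concat(importance, names=["model"]).to_csv(p_imp, sep="\t")
    state.artifacts["evaluation"] = report
    state.manifest.record("evaluate", {"evaluation_report": p_rep,
                                       "importance": p_imp})


STAGE_FUNCS = {"simulate": stage_simulate, "baseline": stage_baseline,
               "gwas": stage_gwas, "expand": stage_expand,
               "reduce": stage_reduce, "select": stage_select,
               "evaluate": stage_evaluate}


def run_pipeline(config: StudyConfig, out_dir, stages=STAGE_ORDER,
                 inputs: dict | None = None, **simulate_kwargs
                 ) -> PipelineState:
    """Execute the requested stages in canonical order.

    ``inputs`` may pre-populate artifacts (e.g. externally loaded
    genotypes and phenotypes) instead of the simulate stage.
    """
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    state = PipelineState(out_dir, config)
    if inputs:
        state.artifacts.update(inputs)
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        if stage == "simulate":
            stage_simulate(state, **simulate_kwargs)
        else:
            STAGE_FUNCS[stage](state)
    state.manifest.save(state.out / "manifest.json")
    return state
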