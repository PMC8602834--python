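"""End-to-end orchestration of the signature workflow.

``run_pipeline`` executes the enabled stages in dependency order —
simulate, gate/filter, derive, clonality, score/evaluate, refine,
response — from a single :class:`PipelineConfig`, writes every artifact
under the output directory, and returns a machine-readable report. A
single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` so any stage can
be re-run in isolation with the seed recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as rio
from .clonality import ClonalityConfig, classify_clonality, clonality_composition, rarefied_entropy
from .cohort import response_auc
from .datatypes import GeneSignature, ValidationError
from .derivation import derive_signature, gene_auc, wilcoxon_markers
from .refinement import stepwise_aic_refine
from .scoring import ScoringConfig, score_samples
from .survival import (
    EvalConfig,
    concordance_index,
    cox_fit,
    logrank_test,
    rmst_ratio,
    score_to_risk,
    stratify_median,
    time_dependent_auc,
)
from .synthetic import (
    CohortDesign,
    ScDesign,
    TcrDesign,
    gen_bulk_cohort,
    gen_response_cohort,
    gen_sc_dataset,
    gen_tcr_table,
)

__version__ = "0.1.0"

_STAGE_INDEX = {"simulate": 0, "derive": 1, "clonality": 2, "survival": 3, "refine": 4, "response": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of the full synthetic-to-report workflow."""

    out_dir: str = "reactsig_out"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "derive", "clonality", "survival", "refine", "response"]
    )
    sc_design: ScDesign = field(default_factory=ScDesign)
    tcr_design: TcrDesign = field(default_factory=TcrDesign)
    cohort_design: CohortDesign = field(default_factory=CohortDesign)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    clonality: ClonalityConfig = field(default_factory=ClonalityConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    derive_k: int = 20
    derive_fdr: float = 0.05
    target_state: str | None = None  # default: the simulated reactive state
    expr_path: str | None = None  # external inputs when simulation is off
    annotation_path: str | None = None
    expr_scale: str = "log2"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in [
            ("sc_design", ScDesign),
            ("tcr_design", TcrDesign),
            ("cohort_design", CohortDesign),
            ("scoring", ScoringConfig),
            ("clonality", ClonalityConfig),
            ("evaluation", EvalConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGE_INDEX)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        if "simulate" not in self.stages:
            for p in (self.expr_path, self.annotation_path):
                if p is None or not Path(p).exists():
                    raise ValidationError(
                        f"simulation disabled but input path missing: {p!r}"
                    )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all enabled stages; write artifacts and return the report dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    current_stage = "setup"
    try:
        # --- simulate or load ------------------------------------------------
        current_stage = "simulate"
        if "simulate" in cfg.stages:
            sc = ScDesign(**{**asdict(cfg.sc_design), "seed": stage_seed(cfg.seed, "simulate")})
            expr, ann = gen_sc_dataset(sc)
            rio.write_expression(expr, out / "sc_expression.tsv")
            rio.write_table(ann.table, out / "sc_annotation.tsv")
            rio.write_json(ann.truth, out / "sc_truth.json")
            report["stages"]["simulate"] = {
                "seed": sc.seed,
                "n_genes": expr.shape[0],
                "n_cells": expr.shape[1],
            }
        else:
            expr = rio.read_expression(cfg.expr_path, scale=cfg.expr_scale)
            ann_table = rio.read_table(cfg.annotation_path)
            from .datatypes import CellAnnotation

            ann = CellAnnotation(table=ann_table)

        target = cfg.target_state or ann.truth.get("reactive_state")
        if target is None:
            raise ValidationError("target_state required when annotation has no truth")

        # --- derive ----------------------------------------------------------
        signature: GeneSignature | None = None
        if "derive" in cfg.stages:
            current_stage = "derive"
            markers = wilcoxon_markers(expr, ann.states(), target, alpha_fdr=cfg.derive_fdr)
            aucs = gene_auc(expr, ann.states(), target)
            signature = derive_signature(markers, aucs, k=cfg.derive_k, source=str(target))
            rio.write_gmt(signature, out / "signature.gmt")
            rio.write_signature_table(signature, out / "signature.tsv")
            stage: dict[str, Any] = {
                "n_genes": len(signature),
                "genes": list(signature.genes),
            }
            if "planted_genes" in ann.truth:
                planted = set(ann.truth["planted_genes"])
                stage["planted_overlap"] = len(planted & set(signature.genes))
            report["stages"]["derive"] = stage

        # --- clonality -------------------------------------------------------
        if "clonality" in cfg.stages:
            current_stage = "clonality"
            tcr = TcrDesign(
                **{**asdict(cfg.tcr_design), "seed": stage_seed(cfg.seed, "clonality")}
            )
            ctable = gen_tcr_table(ann, tcr)
            clon_cfg = ClonalityConfig(
                **{**asdict(cfg.clonality), "seed": stage_seed(cfg.seed, "clonality")}
            )
            ctable = classify_clonality(ctable, clon_cfg)
            rio.write_table(ctable.table, out / "clonotypes.tsv")
            comp = clonality_composition(ctable)
            ent = rarefied_entropy(ctable, clon_cfg)
            rio.write_table(ent, out / "clonality_entropy.tsv")
            by_state = clonality_composition(ctable, by="state")
            frac_clonal = (by_state["clonal"] / by_state.sum(axis=1)).to_dict()
            report["stages"]["clonality"] = {
                "seed": tcr.seed,
                "composition": comp.iloc[0].to_dict(),
                "clonal_fraction_by_state": frac_clonal,
                "entropy_mean": float(ent["entropy_mean"].mean()),
            }

        # --- survival cohort -------------------------------------------------
        bulk = surv = latent = None
        if "survival" in cfg.stages or "refine" in cfg.stages:
            if signature is None:
                raise ValidationError("survival stages need a derived signature")
            current_stage = "survival"
            cd = CohortDesign(
                **{**asdict(cfg.cohort_design), "seed": stage_seed(cfg.seed, "survival")}
            )
            bulk, surv, latent = gen_bulk_cohort(cd, signature)
            rio.write_expression(bulk, out / "bulk_expression.tsv")
            rio.write_table(surv, out / "bulk_survival.tsv")
        if "survival" in cfg.stages:
            sv = score_samples(bulk, signature, cfg.scoring)
            rio.write_table(sv.scores.to_frame(), out / "bulk_scores.tsv")
            grp = stratify_median(sv.scores)
            lr = logrank_test(surv["time"], surv["event"], grp.reindex(surv.index))
            risk = score_to_risk(sv).reindex(surv.index)
            fit = cox_fit(risk, surv["time"], surv["event"], cfg.evaluation)
            cidx = concordance_index(risk, surv["time"], surv["event"])
            t_star = cfg.evaluation.tdauc_time or float(np.median(surv["time"]))
            td = time_dependent_auc(risk, surv["time"], surv["event"], t_star)
            rm = rmst_ratio(surv["time"], surv["event"], grp.reindex(surv.index), cfg.evaluation.rmst_tau)
            report["stages"]["survival"] = {
                "seed": cd.seed,
                "score_method": cfg.scoring.method,
                "logrank_p": lr["p"],
                "cox_hr": float(fit.hr[0]),
                "cox_beta": float(fit.beta[0]),
                "c_index": cidx,
                "tdauc": td,
                "tdauc_time": t_star,
                "rmst": rm,
                "latent_spearman": float(sv.scores.corr(latent, method="spearman")),
            }

        # --- refine ----------------------------------------------------------
        if "refine" in cfg.stages:
            current_stage = "refine"
            refined, trace = stepwise_aic_refine(bulk, signature, surv, cfg.scoring, cfg.evaluation)
            rio.write_gmt(refined, out / "signature_refined.gmt")
            rio.write_table(trace.as_frame(), out / "refinement_trace.tsv", index=False)
            report["stages"]["refine"] = {
                "n_genes_before": len(signature),
                "n_genes_after": len(refined),
                "removed": trace.removed_genes,
                "n_steps": len(trace.steps),
            }

        # --- response --------------------------------------------------------
        if "response" in cfg.stages:
            if signature is None:
                raise ValidationError("response stage needs a derived signature")
            current_stage = "response"
            cd = CohortDesign(
                **{**asdict(cfg.cohort_design), "seed": stage_seed(cfg.seed, "response")}
            )
            rexpr, labels, _ = gen_response_cohort(cd, signature)
            sv = score_samples(rexpr, signature, cfg.scoring)
            table = pd.DataFrame({"responder": labels, "score": sv.scores})
            rio.write_table(table, out / "response_scores.tsv")
            res = response_auc(table)
            report["stages"]["response"] = {
                "seed": cd.seed,
                "auc": res["auc"],
                "ranksum_p": res["ranksum_p"],
                "n_responders": res["n_responders"],
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current_stage}: {exc}\n")
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    rio.write_json(report, out / "report.json")
    return report
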