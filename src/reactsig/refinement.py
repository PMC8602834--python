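"""Backward elimination of signature genes under a univariate Cox AIC.

The loop scores the cohort on the current gene set, fits a univariate Cox
model on the score (AIC0), then tries every single-gene deletion,
re-scoring the remaining set and refitting the Cox model each time. The
deletion with the lowest AIC is accepted if it is strictly below AIC0;
ties break lexicographically. The loop stops when no deletion strictly
decreases the AIC. Because every fit has exactly one coefficient, an AIC
decrease is equivalent to a partial log-likelihood increase; this
equivalence is asserted on every accepted step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .datatypes import ExpressionMatrix, GeneSignature, ValidationError, validate_survival
from .scoring import ScoringConfig, kernel_cdf_stat, score_samples
from .survival import EvalConfig, cox_fit


@dataclass
class RefinementTrace:
    """Accepted deletions in order, with per-step AIC bookkeeping."""

    steps: list[dict[str, Any]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def removed_genes(self) -> list[str]:
        return [s["gene_removed"] for s in self.steps]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _score_and_aic(
    expr: ExpressionMatrix,
    genes: list[str],
    survival: pd.DataFrame,
    scoring_cfg: ScoringConfig,
    eval_cfg: EvalConfig,
    kernel_stat=None,
) -> tuple[float, float]:
    sig = GeneSignature(genes=list(genes))
    sv = score_samples(expr, sig, scoring_cfg, kernel_stat=kernel_stat)
    scores = sv.scores.reindex(survival.index)
    fit = cox_fit(scores, survival["time"], survival["event"], eval_cfg)
    if not fit.converged:
        raise ValidationError("Cox fit did not converge")
    return fit.aic, fit.loglik


def stepwise_aic_refine(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    survival: pd.DataFrame,
    scoring_cfg: ScoringConfig | None = None,
    eval_cfg: EvalConfig | None = None,
) -> tuple[GeneSignature, RefinementTrace]:
    """Refine a signature by stepwise AIC backward elimination.

    Returns the refined signature (a subset of the input, never empty) and
    the full trace. Deterministic given inputs and configuration. A Cox
    non-convergence on a candidate deletion skips that candidate with a
    trace note; if every candidate fails, the loop stops with a warning.
    """
    scoring_cfg = scoring_cfg or ScoringConfig(method="kcdf_ks")
    eval_cfg = eval_cfg or EvalConfig()
    validate_survival(survival)
    if len(signature) == 0:
        raise ValidationError("empty signature")
    trace = RefinementTrace()
    current = list(signature.genes)
    if len(current) == 1:
        return signature, trace

    # the kernel transform depends only on the matrix, not the gene set:
    # compute it once and reuse it across every candidate deletion
    kernel_stat = (
        kernel_cdf_stat(expr, scoring_cfg.kernel) if scoring_cfg.method == "kcdf_ks" else None
    )
    aic0, ll0 = _score_and_aic(expr, current, survival, scoring_cfg, eval_cfg, kernel_stat)
    while len(current) > 1:
        candidates: list[tuple[float, float, str]] = []
        for g in sorted(current):
            remaining = [x for x in current if x != g]
            try:
                aic_g, ll_g = _score_and_aic(
                    expr, remaining, survival, scoring_cfg, eval_cfg, kernel_stat
                )
            except ValidationError as exc:
                trace.notes.append(f"candidate deletion of {g} skipped: {exc}")
                continue
            candidates.append((aic_g, ll_g, g))
        if not candidates:
            trace.notes.append("all candidate deletions failed; stopping")
            break
        # lowest AIC wins; the sort key's gene id settles exact ties
        best_aic, best_ll, best_gene = min(candidates, key=lambda c: (c[0], c[2]))
        if not best_aic < aic0:
            break
        assert best_ll > ll0, "AIC decrease must coincide with log-likelihood increase"
        current = [x for x in current if x != best_gene]
        trace.steps.append(
            {
                "gene_removed": best_gene,
                "aic_before": aic0,
                "aic_after": best_aic,
                "loglik_before": ll0,
                "loglik_after": best_ll,
                "remaining": list(current),
                "score_method": scoring_cfg.method,
            }
        )
        aic0, ll0 = best_aic, best_ll

    refined = GeneSignature(
        genes=[g for g in signature.genes if g in current],
        auc={g: a for g, a in signature.auc.items() if g in current},
        k=signature.k,
        provenance={
            **signature.provenance,
            "refined_from": len(signature),
            "removed": trace.removed_genes,
        },
    )
    return refined, trace
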