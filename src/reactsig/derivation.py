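"""Signature derivation: rank-sum markers and one-vs-rest AUROC ranking.

Candidate markers of the target (reactive) state are genes significantly
higher in that state by a one-sided Wilcoxon rank-sum test (BH-adjusted
p < 0.05 by default). Each candidate is then scored by the area under the
one-vs-rest ROC curve — the probability, with ties counted half, that a
target-state cell expresses the gene above a non-target cell — and the
signature is the top ``k`` candidates by AUC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSignature, ValidationError


def _split(expr: ExpressionMatrix, labels: pd.Series, target) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(expr.observations)
    in_target = (labels == target).to_numpy()
    if in_target.sum() == 0:
        raise ValidationError(f"target state {target!r} absent from labels")
    if (~in_target).sum() == 0:
        raise ValidationError("no observations outside the target state")
    x = expr.values.to_numpy(dtype=float)
    return x[:, in_target], x[:, ~in_target]


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "greater",
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Wilcoxon rank-sum tests of ``x`` (target) vs ``y`` (rest).

    Uses exact enumeration when the combined group size is at most 20 and
    the row has no ties; otherwise the normal approximation with midranks,
    tie correction and continuity correction. Returns (statistic, p).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 1 or n2 < 1:
        raise ValidationError("both groups must be non-empty")
    small = (n1 + n2) <= 20
    stat = np.empty(x.shape[0])
    pval = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        xi, yi = x[i], y[i]
        if np.ptp(np.concatenate([xi, yi])) == 0:
            # constant row carries no ordering information
            stat[i], pval[i] = n1 * n2 / 2.0, 1.0
            continue
        has_ties = len(np.unique(np.concatenate([xi, yi]))) < n1 + n2
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(xi, yi, alternative=alternative, method=method)
        stat[i], pval[i] = res.statistic, res.pvalue
    return stat, pval


def wilcoxon_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    target,
    alpha_fdr: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-gene rank-sum marker test of the target state vs all others.

    Returns a table indexed by gene with columns ``statistic``, ``pvalue``,
    ``fdr`` (BH step-up over all tested genes), ``mean_target``,
    ``mean_rest``, ``up_in_target`` and ``candidate`` (FDR < ``alpha_fdr``).
    """
    xt, xr = _split(expr, labels, target)
    if xt.shape[1] < 2 or xr.shape[1] < 2:
        raise ValidationError("need at least 2 observations inside and outside the target")
    stat, pval = rank_sum_test(xt, xr, alternative=alternative)
    fdr = stats.false_discovery_control(pval, method="bh")
    mean_t = xt.mean(axis=1)
    mean_r = xr.mean(axis=1)
    table = pd.DataFrame(
        {
            "statistic": stat,
            "pvalue": pval,
            "fdr": fdr,
            "mean_target": mean_t,
            "mean_rest": mean_r,
            "up_in_target": mean_t > mean_r,
            "candidate": fdr < alpha_fdr,
        },
        index=expr.genes,
    )
    return table


def auc_from_groups(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise pair-counting AUC with ties counted half (midrank identity)."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    n1, n2 = pos.shape[1], neg.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.hstack([pos, neg])
    ranks = stats.rankdata(combined, axis=1)  # midranks
    r1 = ranks[:, :n1].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def gene_auc(expr: ExpressionMatrix, labels: pd.Series, target) -> pd.Series:
    """One-vs-rest ROC AUC per gene for discriminating the target state."""
    xt, xr = _split(expr, labels, target)
    return pd.Series(auc_from_groups(xt, xr), index=expr.genes, name="auc")


def derive_signature(
    markers: pd.DataFrame,
    aucs: pd.Series,
    k: int = 20,
    source: str | None = None,
) -> GeneSignature:
    """Select the top-``k`` candidate marker genes by one-vs-rest AUC.

    Only FDR-passing genes higher in the target are eligible. Ties at the
    boundary AUC break lexicographically by gene id. If fewer than ``k``
    candidates exist, all are returned and a warning is recorded in the
    signature's provenance.
    """
    if not markers.index.equals(aucs.index):
        aucs = aucs.reindex(markers.index)
        if aucs.isna().any():
            raise ValidationError("markers and AUCs cover different gene universes")
    eligible = markers.index[(markers["candidate"]) & (markers["up_in_target"])]
    if len(eligible) == 0:
        raise ValidationError("no candidate marker genes; nothing to select")
    order = sorted(eligible, key=lambda g: (-aucs[g], g))
    chosen = order[:k]
    provenance: dict = {"source_cluster": source, "k_requested": k}
    if len(chosen) < k:
        provenance["warning"] = f"only {len(chosen)} candidates available for k={k}"
    return GeneSignature(
        genes=list(chosen),
        auc={g: float(aucs[g]) for g in chosen},
        k=k,
        provenance=provenance,
    )
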