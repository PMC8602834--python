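"""Group-level cohort statistics: rank tests, response ROC, DE, Spearman.

These are the evaluation statistics applied to scored cohorts: a global
Kruskal–Wallis test with pairwise rank-sum follow-ups across score groups,
responder-vs-score ROC analysis for immunotherapy response, the two-group
Welch-t differential-expression rule (|log2FC| and BH FDR thresholds), and
Spearman rank association.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, ValidationError
from .derivation import auc_from_groups, rank_sum_test


@dataclass
class DEConfig:
    """Differential-expression rule: |log2FC| > lfc AND FDR < fdr (Welch t)."""

    lfc_threshold: float = 1.5
    fdr_threshold: float = 0.01
    signed: bool = False  # when True, only up-regulation passes the LFC rule

    def validate(self) -> None:
        if self.lfc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValidationError("DE thresholds must be positive")


def rank_tests(scores, groups) -> dict:
    """Kruskal–Wallis across all groups plus pairwise two-sided rank-sum p's.

    Pairwise p-values are reported unadjusted (the convention behind the
    usual per-pair significance stars); apply a correction downstream if
    global error control across pairs is needed.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    labels = sorted(np.unique(g).tolist())
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [s[g == lab] for lab in labels]
    if any(len(x) == 0 for x in samples):
        raise ValidationError("empty group")
    if np.ptp(s) == 0:
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*samples)
    pair_p = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            _, p = rank_sum_test(samples[i][None, :], s[g == b][None, :], alternative="two-sided")
            pair_p.loc[a, b] = pair_p.loc[b, a] = float(p[0])
    return {"kw_statistic": float(kw_stat), "kw_p": float(kw_p), "pairwise_p": pair_p}


def response_auc(table: pd.DataFrame) -> dict:
    """ROC analysis of a score predicting responder status.

    ``table`` needs columns ``responder`` (0/1) and ``score``. Returns the
    pair-counting AUC (responders positive), a two-sided rank-sum p-value,
    and the sample ordering by descending score for waterfall plots.
    """
    missing = {"responder", "score"} - set(table.columns)
    if missing:
        raise ValidationError(f"response table missing columns {sorted(missing)}")
    resp = np.asarray(table["responder"], dtype=int)
    score = np.asarray(table["score"], dtype=float)
    pos, neg = score[resp == 1], score[resp == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both responder classes must be present")
    auc = float(auc_from_groups(pos[None, :], neg[None, :])[0])
    _, p = rank_sum_test(pos[None, :], neg[None, :], alternative="two-sided")
    order = table.sort_values("score", ascending=False).index.tolist()
    return {"auc": auc, "ranksum_p": float(p[0]), "waterfall_order": order,
            "n_responders": int(len(pos)), "n_nonresponders": int(len(neg))}


def group_de(expr: ExpressionMatrix, groups, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Two-group Welch-t differential expression on log2-scale input.

    log2FC is the difference of group means (group2 - group1 on sorted
    labels); significance requires |log2FC| above the threshold (signed
    mode: log2FC itself) and BH FDR below the threshold.
    """
    cfg = cfg or DEConfig()
    cfg.validate()
    if expr.scale != "log2":
        raise ValidationError("group_de expects a log2-scale matrix")
    g = pd.Series(groups)
    if not g.index.equals(expr.observations):
        g = g.reindex(expr.observations)
    labels = sorted(g.dropna().unique().tolist())
    if len(labels) != 2:
        raise ValidationError("exactly 2 groups required")
    x = expr.values.to_numpy(dtype=float)
    m1 = (g == labels[0]).to_numpy()
    m2 = (g == labels[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError("each group needs at least 2 samples")
    t_stat, pvals = stats.ttest_ind(x[:, m2], x[:, m1], axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    lfc = x[:, m2].mean(axis=1) - x[:, m1].mean(axis=1)
    fdr = stats.false_discovery_control(pvals, method="bh")
    passes_lfc = lfc > cfg.lfc_threshold if cfg.signed else np.abs(lfc) > cfg.lfc_threshold
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t_stat,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": passes_lfc & (fdr < cfg.fdr_threshold),
            "direction": np.where(lfc > 0, f"up_in_{labels[1]}", f"up_in_{labels[0]}"),
        },
        index=expr.genes,
    )
    out.attrs["groups"] = labels
    return out


def spearman_assoc(x, y, exact: bool = False) -> dict[str, float]:
    """Spearman rank correlation with a t-approximation p-value.

    ``exact=True`` (n <= 10, intended for verification at small n)
    enumerates all rank permutations for the p-value instead.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValidationError("need equal-length inputs with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(xa, ya)
    if exact:
        n = xa.size
        if n > 10:
            raise ValidationError("exact enumeration limited to n <= 10")
        rx = stats.rankdata(xa)
        ry = stats.rankdata(ya)
        obs = abs(rho)
        count, total = 0, 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return {"rho": float(rho), "p": float(p)}
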