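"""Single-sample and single-cell gene-set scoring.

Five per-sample statistics quantify how strongly a sample expresses a
signature:

* ``kcdf_ks`` — kernel-CDF transform of each gene across samples followed
  by a rank-weighted Kolmogorov–Smirnov random walk (the GSVA statistic);
* ``rank_weighted_ks`` — per-sample rank-weighted KS walk summed over the
  whole list (the ssGSEA statistic);
* ``combined_z`` — per-gene z-scores summed over the set and divided by
  sqrt(k);
* ``first_singular_vector`` — entries of the first right singular vector of
  the z-scored signature submatrix (the PLAGE statistic), sign-oriented here
  so that it correlates non-negatively with the mean signature z-score;
* ``mean`` — plain mean expression of the signature genes.

For single cells the ranking-recovery statistic (AUCell) scores each cell
by the area under the curve of signature genes recovered within the
top-ranked fraction of that cell's genes, normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSignature, ScoreVector, ValidationError

METHODS = (
    "kcdf_ks",
    "rank_weighted_ks",
    "combined_z",
    "first_singular_vector",
    "mean",
)


@dataclass
class ScoringConfig:
    """Parameters of the scoring statistics.

    kernel
        ``gaussian`` (bandwidth s_i / 4 per gene) for log/continuous data or
        ``poisson`` (rate x + 0.5) for raw counts; used by ``kcdf_ks`` only.
    tau
        Rank-weight exponent of the kcdf_ks walk.
    es_mode
        ``max_diff``: largest positive walk deviation minus largest absolute
        negative deviation; ``max_abs``: single maximum-magnitude deviation.
    rwks_alpha / rwks_normalize
        Rank-weight exponent of the rank_weighted_ks walk and whether to
        divide the cohort's scores by their range.
    recovery_top_fraction
        Fraction of the gene list defining the ranking-recovery threshold.
    tie_break
        ``random`` (seeded) or ``first`` for deterministic per-cell ranking.
    """

    method: str = "kcdf_ks"
    kernel: str = "gaussian"
    tau: float = 1.0
    es_mode: str = "max_diff"
    rwks_alpha: float = 0.25
    rwks_normalize: bool = True
    recovery_top_fraction: float = 0.05
    orient_singular_vector: bool = True
    tie_break: str = "random"
    seed: int = 0

    def validate(self) -> None:
        if self.kernel not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.es_mode not in ("max_diff", "max_abs"):
            raise ValidationError(f"unknown es_mode {self.es_mode!r}")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if not (0.0 < self.recovery_top_fraction < 1.0):
            raise ValidationError("recovery_top_fraction must lie in (0, 1)")
        if self.tie_break not in ("random", "first"):
            raise ValidationError(f"unknown tie_break {self.tie_break!r}")

    def snapshot(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def kernel_cdf_stat(expr: ExpressionMatrix, kernel: str = "gaussian") -> pd.DataFrame:
    """Kernel cumulative-density transform of each gene across samples.

    For gene i and sample j the statistic is the mean over samples k of a
    kernel CDF at x_ij: Gaussian Phi((x_ij - x_ik) / h_i) with bandwidth
    h_i = s_i / 4, or the Poisson CDF at x_ij with rate x_ik + 0.5 for
    count data. Genes with zero variance are assigned the constant 0.5 row.
    """
    x = expr.values.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 3:
        raise ValidationError("kernel CDF estimate needs at least 3 samples")
    out = np.empty_like(x)
    if kernel == "gaussian":
        sd = x.std(axis=1, ddof=1)
        for i in range(x.shape[0]):
            if sd[i] == 0 or not np.isfinite(sd[i]):
                out[i] = 0.5
                continue
            h = sd[i] / 4.0
            diff = (x[i][:, None] - x[i][None, :]) / h  # (x_ij - x_ik)
            out[i] = stats.norm.cdf(diff).mean(axis=1)
    elif kernel == "poisson":
        if np.any(x < 0):
            raise ValidationError("poisson kernel requires nonnegative values")
        for i in range(x.shape[0]):
            if np.ptp(x[i]) == 0:
                out[i] = 0.5
                continue
            rate = x[i][None, :] + 0.5  # rate per reference sample k
            out[i] = stats.poisson.cdf(x[i][:, None], rate).mean(axis=1)
    else:
        raise ValidationError(f"unknown kernel {kernel!r}")
    return pd.DataFrame(out, index=expr.genes, columns=expr.observations)


def _present_signature(expr: ExpressionMatrix, signature: GeneSignature) -> list[str]:
    present = [g for g in signature.genes if g in expr.genes]
    if not present:
        raise ValidationError(
            f"no signature gene present in matrix; missing: {signature.genes}"
        )
    return present


def _kcdf_ks_walk(z_col: np.ndarray, in_set: np.ndarray, tau: float, es_mode: str) -> float:
    """Weighted KS walk over genes ranked by the kernel statistic.

    Genes are ranked by z descending; the walk weight of a set gene at rank
    r is |p/2 - r| ** tau (symmetrized rank), out-of-set steps are uniform.
    """
    p = z_col.size
    order = np.argsort(-z_col, kind="stable")
    ranks = np.empty(p, dtype=float)
    ranks[order] = np.arange(1, p + 1)
    sym = np.abs(p / 2.0 - ranks)
    w = np.where(in_set, sym**tau, 0.0)
    w_total = w.sum()
    n_out = p - int(in_set.sum())
    if w_total == 0 or n_out == 0:
        raise ValidationError("degenerate gene set for kcdf_ks walk")
    inc_in = w[order] / w_total
    inc_out = np.where(in_set[order], 0.0, 1.0 / n_out)
    walk = np.cumsum(inc_in - inc_out)
    if es_mode == "max_diff":
        return float(max(walk.max(), 0.0) - max(-walk.min(), 0.0))
    return float(walk[np.argmax(np.abs(walk))])


def _rank_weighted_ks_walk(x_col: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA-style walk: sum of running ECDF differences down the ranked list."""
    p = x_col.size
    n_in = int(in_set.sum())
    if n_in == p:
        raise ValidationError("signature equals the whole gene universe")
    ranks = stats.rankdata(x_col)  # ascending midranks: highest expression = p
    order = np.argsort(-x_col, kind="stable")
    w = np.where(in_set, ranks**alpha, 0.0)
    w_total = w[in_set].sum()
    inc_in = w[order] / w_total
    inc_out = np.where(in_set[order], 0.0, 1.0 / (p - n_in))
    return float((np.cumsum(inc_in) - np.cumsum(inc_out)).sum())


def score_samples(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    cfg: ScoringConfig | None = None,
    kernel_stat: pd.DataFrame | None = None,
) -> ScoreVector:
    """Score each sample of a bulk matrix by the configured statistic.

    ``kernel_stat`` lets callers that score many signatures on one matrix
    (e.g. the refinement loop) reuse a precomputed :func:`kernel_cdf_stat`
    result; it is ignored by the other methods.
    """
    cfg = cfg or ScoringConfig()
    cfg.validate()
    if cfg.method not in METHODS:
        raise ValidationError(f"unknown scoring method {cfg.method!r}")
    present = _present_signature(expr, signature)
    x = expr.values.to_numpy(dtype=float)
    in_set = np.asarray(expr.genes.isin(present))
    obs = expr.observations

    if cfg.method == "kcdf_ks":
        if kernel_stat is None:
            kernel_stat = kernel_cdf_stat(expr, cfg.kernel)
        z = kernel_stat.to_numpy()
        scores = np.array(
            [_kcdf_ks_walk(z[:, j], in_set, cfg.tau, cfg.es_mode) for j in range(z.shape[1])]
        )
    elif cfg.method == "rank_weighted_ks":
        scores = np.array(
            [
                _rank_weighted_ks_walk(x[:, j], in_set, cfg.rwks_alpha)
                for j in range(x.shape[1])
            ]
        )
        if cfg.rwks_normalize:
            rng_ = scores.max() - scores.min()
            if rng_ > 0:
                scores = scores / rng_
    elif cfg.method == "combined_z":
        z = _zscore_rows(x[in_set])
        scores = z.sum(axis=0) / np.sqrt(in_set.sum())
    elif cfg.method == "first_singular_vector":
        z = _zscore_rows(x[in_set])
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0]
        if cfg.orient_singular_vector:
            ref = z.mean(axis=0)
            if np.dot(scores - scores.mean(), ref - ref.mean()) < 0:
                scores = -scores
    else:  # mean
        scores = x[in_set].mean(axis=0)

    return ScoreVector(
        scores=pd.Series(scores, index=obs, name="score"),
        method=cfg.method,
        config=cfg.snapshot(),
    )


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("zero-variance gene in signature; cannot z-score")
    return (x - mu) / sd


def score_cells_ranking_recovery(
    expr: ExpressionMatrix, signature: GeneSignature, cfg: ScoringConfig | None = None
) -> ScoreVector:
    """Ranking-recovery (AUCell) score per cell.

    Genes are ranked per cell by expression descending (ties broken by a
    seeded shuffle, or by first occurrence in deterministic mode). With
    threshold T = ceil(top_fraction * n_genes), the score is the area under
    the step curve counting signature genes recovered at each rank 1..T,
    normalized by the maximal achievable area.
    """
    import warnings

    cfg = cfg or ScoringConfig(method="ranking_recovery")
    cfg.validate()
    present = _present_signature(expr, signature)
    x = expr.values.to_numpy(dtype=float)
    p, n = x.shape
    k = len(present)
    t_thr = int(np.ceil(cfg.recovery_top_fraction * p))
    if k > t_thr:
        warnings.warn(
            f"signature size {k} exceeds ranking threshold {t_thr}; "
            "scores cannot reach 1 (raise recovery_top_fraction to widen)",
            stacklevel=2,
        )
    in_set = np.asarray(expr.genes.isin(present))
    rng = np.random.default_rng(cfg.seed)
    max_area = np.minimum(np.arange(1, t_thr + 1), k).sum()
    scores = np.empty(n)
    for j in range(n):
        if cfg.tie_break == "random":
            jitter = rng.permutation(p)
            order = np.lexsort((jitter, -x[:, j]))
        else:
            order = np.argsort(-x[:, j], kind="stable")
        hits = np.cumsum(in_set[order][:t_thr])
        scores[j] = hits.sum() / max_area
    return ScoreVector(
        scores=pd.Series(scores, index=expr.observations, name="score"),
        method="ranking_recovery",
        config=cfg.snapshot(),
    )
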