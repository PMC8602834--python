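"""Survival machinery: KM, log-rank, Cox PH and the comparison metrics.

All estimators are implemented directly so their conventions are explicit
and oracle-checkable:

* Kaplan–Meier product-limit curves with Greenwood terms;
* the k-group log-rank test;
* Cox proportional hazards by Newton–Raphson on the Efron-ties partial
  likelihood (Breslow available), with SEs from observed information;
* Harrell's concordance index over usable pairs;
* cumulative-case / dynamic-control time-dependent ROC AUC with
  Kaplan–Meier censoring weighting;
* restricted mean survival time by exact step integration with a
  Greenwood/delta-method CI on the log scale, compared across arms as a
  ratio.

Risk direction convention: higher risk = worse survival throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, ScoreVector, ValidationError


@dataclass
class EvalConfig:
    """Shared evaluation settings (ties rule, horizons, bootstrap reps)."""

    ties: str = "efron"
    tdauc_time: float | None = None
    rmst_tau: float | None = None
    bootstrap_reps: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.ties not in ("efron", "breslow"):
            raise ValidationError(f"unknown ties method {self.ties!r}")


@dataclass
class KMCurve:
    """Product-limit estimate with the pieces needed downstream."""

    event_times: np.ndarray  # distinct times with >= 1 event
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_time: float
    median: float | None

    def at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty survival data")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValidationError("survival times must be positive and finite")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("event flags must be 0/1")
    return t, e


def km_curve(times, events) -> KMCurve:
    """Kaplan–Meier estimate; median = first time S(t) <= 0.5 (or None)."""
    t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, d_i = np.unique(t[e == 1], return_counts=True)
    n_i = t.size - np.searchsorted(t, uniq, side="left")
    surv_arr = np.cumprod(1.0 - d_i / n_i)
    n_risk, n_ev = n_i, d_i
    median = None
    below = np.nonzero(surv_arr <= 0.5)[0] if surv_arr.size else np.array([], dtype=int)
    if below.size:
        median = float(uniq[below[0]])
    return KMCurve(
        event_times=uniq,
        survival=surv_arr,
        n_at_risk=np.asarray(n_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        max_time=float(t.max()),
        median=median,
    )


def logrank_test(times, events, groups) -> dict[str, float]:
    """k-group log-rank test over pooled event times.

    Returns the chi-square statistic, its degrees of freedom (k - 1) and
    the upper-tail p-value.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValidationError("need at least 2 groups")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ValidationError(f"group {lab!r} is empty")
    if e.sum() == 0:
        raise ValidationError("no events observed")

    event_times = np.unique(t[e == 1])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in event_times:
        at_risk = t >= ti
        n = at_risk.sum()
        d = ((t == ti) & (e == 1)).sum()
        n_g = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        d_g = np.array([((t == ti) & (e == 1) & (g == lab)).sum() for lab in labels])
        expected = d * n_g / n
        o_minus_e += d_g - expected
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += v
    z = o_minus_e[:-1]
    v = cov[:-1, :-1]
    statistic = float(z @ np.linalg.pinv(v) @ z)
    df = k - 1
    return {"statistic": statistic, "df": df, "p": float(stats.chi2.sf(statistic, df))}


@dataclass
class CoxFit:
    """Cox PH fit summary (per-covariate arrays aligned with ``names``)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        z = stats.norm.ppf(0.975)
        return np.exp(
            np.stack([self.beta - z * self.se, self.beta + z * self.se], axis=1)
        )

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)

    @property
    def p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def _cox_loglik_grad_hess(
    beta: np.ndarray, x: np.ndarray, t: np.ndarray, e: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron (or Breslow) partial log-likelihood with derivatives.

    Risk-set sums are suffix cumulative sums over the time-sorted data, so
    the cost is O(n p^2) plus a cheap loop over distinct event times.
    """
    n, p = x.shape
    order = np.argsort(t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    eta = xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * xs
    wxx = wx[:, :, None] * xs[:, None, :]
    # suffix sums: index i holds the sum over all subjects with time >= ts[i]
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1], axis=0)[::-1]
    cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]
    uniq, first, counts = np.unique(ts, return_index=True, return_counts=True)
    loglik, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for ui in range(uniq.size):
        i0 = first[ui]
        block = slice(i0, i0 + counts[ui])
        dead = es[block] == 1
        d = int(dead.sum())
        if d == 0:
            continue
        s_r, z_r, q_r = cw[i0], cwx[i0], cwxx[i0]
        loglik += eta[block][dead].sum()
        grad += xs[block][dead].sum(axis=0)
        if d == 1:
            ls = np.zeros(1)
            s_d = z_d = q_d = 0.0
        else:
            ls = np.arange(d) / d if ties == "efron" else np.zeros(d)
            s_d = w[block][dead].sum()
            z_d = wx[block][dead].sum(axis=0)
            q_d = wxx[block][dead].sum(axis=0)
        for l in ls:
            phi = s_r - l * s_d
            zz = z_r - l * z_d
            qq = q_r - l * q_d
            loglik -= np.log(phi)
            grad -= zz / phi
            hess -= qq / phi - np.outer(zz, zz) / phi**2
    return loglik, grad, hess


def cox_fit(
    covariates,
    times,
    events,
    cfg: EvalConfig | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    ``covariates`` may be a Series, DataFrame or array (observations x
    covariates). Convergence requires the max absolute score component to
    fall below ``tol``; step halving guards against overshoot. Monotone
    partial likelihood (perfect separation) is flagged and the coefficient
    reported capped rather than diverging.
    """
    cfg = cfg or EvalConfig()
    cfg.validate()
    t, e = _as_arrays(times, events)
    if e.sum() == 0:
        raise ValidationError("no events: Cox model cannot be fit")
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        x = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, pd.Series):
        names = [str(covariates.name or "x")]
        x = covariates.to_numpy(dtype=float)[:, None]
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if not np.all(np.isfinite(x)):
        raise ValidationError("covariates must be finite")
    if np.any(x.std(axis=0) == 0):
        raise ValidationError("constant covariate: no information")
    # center for numerical stability; beta is unaffected
    x = x - x.mean(axis=0)

    beta = np.zeros(x.shape[1])
    flags: list[str] = []
    loglik, grad, hess = _cox_loglik_grad_hess(beta, x, t, e, cfg.ties)
    converged = False
    it = 0
    cap = 22.0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")
            break
        if np.max(np.abs(step)) < 1e-12:
            converged = True  # parameter change below float resolution
            break
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, x, t, e, cfg.ties)
        halvings = 0
        ll_floor = loglik - 1e-10 * max(1.0, abs(loglik))
        while new_ll < ll_floor and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, x, t, e, cfg.ties)
            halvings += 1
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > cap:
            flags.append("monotone likelihood suspected; coefficient capped")
            beta = np.clip(beta, -cap, cap)
            loglik, grad, hess = _cox_loglik_grad_hess(beta, x, t, e, cfg.ties)
            break
    else:
        flags.append(f"did not converge in {max_iter} iterations")
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    info = -hess
    try:
        var = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(var), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.nan)
        flags.append("variance not estimable")
    return CoxFit(
        names=names,
        beta=beta,
        se=se,
        loglik=float(loglik),
        n=len(t),
        n_events=int(e.sum()),
        converged=converged,
        n_iter=it,
        flags=flags,
    )


def concordance_index(risk, times, events) -> float:
    """Harrell's C over usable pairs.

    A pair is usable when the subject with the shorter time has an event;
    tied times with both events are unusable; tied times with exactly one
    event count the event subject as the shorter. Risk ties score half.
    """
    r = np.asarray(risk, dtype=float)
    t, e = _as_arrays(times, events)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None].astype(bool), e[None, :].astype(bool)
    ri, rj = r[:, None], r[None, :]
    # "i shorter with event": strictly earlier event, or tied time where
    # only i has the event (the censored subject outlived the failure)
    i_shorter = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    usable = i_shorter  # each unordered usable pair appears exactly once
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValidationError("no usable pair for concordance")
    concordant = (usable & (ri > rj)).sum()
    tied = (usable & (ri == rj)).sum()
    return float((concordant + 0.5 * tied) / n_usable)


def compare_cindex(
    risk_a, risk_b, times, events, n_boot: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Paired-bootstrap comparison of two risk scores' C-indices.

    Resamples subjects with replacement, recomputing both C-indices on each
    replicate; reports the observed difference (a - b), a percentile CI and
    a two-sided bootstrap p-value for zero difference.
    """
    ra, rb = np.asarray(risk_a, float), np.asarray(risk_b, float)
    t, e = _as_arrays(times, events)
    obs = concordance_index(ra, t, e) - concordance_index(rb, t, e)
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(t)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if e[idx].sum() == 0:
            continue
        try:
            diffs.append(
                concordance_index(ra[idx], t[idx], e[idx])
                - concordance_index(rb[idx], t[idx], e[idx])
            )
        except ValidationError:
            continue
    diffs_arr = np.asarray(diffs)
    lo, hi = np.percentile(diffs_arr, [2.5, 97.5])
    p = 2.0 * min((diffs_arr <= 0).mean(), (diffs_arr >= 0).mean())
    return {
        "delta_c": float(obs),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(min(1.0, p)),
        "n_boot": int(diffs_arr.size),
    }


def time_dependent_auc(risk, times, events, t_star: float) -> float:
    """Cumulative-case / dynamic-control AUC at ``t_star``, KM-weighted.

    Sensitivity and specificity at each risk cutpoint are derived from
    Kaplan–Meier survival within the above-cut subset (Bayes inversion),
    and the AUC is the trapezoid integral over the resulting ROC. In the
    absence of censoring before ``t_star`` this reduces to the plain
    empirical AUC of risk against the event-by-t* indicator.
    """
    r = np.asarray(risk, dtype=float)
    t, e = _as_arrays(times, events)
    if t_star <= 0 or t_star > t.max():
        raise ValidationError("t_star must lie within follow-up")
    s_all = km_curve(t, e).at(t_star)
    if s_all >= 1.0:
        raise ValidationError("no case (event by t_star)")
    if s_all <= 0.0:
        raise ValidationError("no control (survivor past t_star)")
    n = len(r)
    cuts = np.unique(r)
    sens = [1.0]
    fpr = [1.0]
    for c in cuts:  # threshold rule: positive iff risk > c
        above = r > c
        p_above = above.mean()
        if p_above == 0:
            s_c = 0.0  # empty subset contributes no mass
            mass = 0.0
        else:
            s_c = km_curve(t[above], e[above]).at(t_star)
            mass = p_above
        se_c = (1.0 - s_c) * mass / (1.0 - s_all)
        sp_c = (s_all - s_c * mass) / s_all
        sens.append(float(np.clip(se_c, 0.0, 1.0)))
        fpr.append(float(np.clip(1.0 - sp_c, 0.0, 1.0)))
    pts = sorted(zip(fpr, sens))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def _rmst_single(times, events, tau: float) -> tuple[float, float]:
    """RMST on [0, tau] by step integration plus its Greenwood variance."""
    t, e = _as_arrays(times, events)
    km = km_curve(t, e)
    # tau past the end of follow-up is fine only if the curve is fully
    # determined there (survival already at zero)
    if tau > t.max() and (km.survival.size == 0 or km.survival[-1] > 0):
        raise ValidationError(
            f"tau {tau} beyond the arm's last observed time {t.max()}; reduce tau"
        )
    grid = np.concatenate([[0.0], km.event_times[km.event_times < tau], [tau]])
    surv = np.concatenate([[1.0], km.survival[km.event_times < tau]])
    rmst = float(np.sum(surv * np.diff(grid)))
    # Greenwood-type variance: sum over event times of (area beyond t_i)^2 * d/(n(n-d))
    var = 0.0
    for i, ti in enumerate(km.event_times):
        if ti >= tau:
            break
        d, n_i = km.n_events[i], km.n_at_risk[i]
        if n_i - d <= 0:
            continue
        mask = grid >= ti
        sub_grid = np.concatenate([[ti], grid[mask & (grid > ti)]])
        sub_surv = surv[np.searchsorted(grid, sub_grid[:-1], side="right") - 1]
        area_beyond = float(np.sum(sub_surv * np.diff(sub_grid)))
        var += area_beyond**2 * d / (n_i * (n_i - d))
    return rmst, var


def rmst_ratio(times, events, groups, tau: float | None = None) -> dict[str, Any]:
    """Per-arm RMST on [0, tau] and their ratio (arm2 / arm1) with a CI.

    ``tau`` defaults to the minimum over arms of the maximum observed time.
    The CI comes from the delta method on log-RMST with Greenwood variances.
    Arm order follows the sorted group labels and is reported explicitly.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = sorted(np.unique(g).tolist())
    if len(labels) != 2:
        raise ValidationError("rmst_ratio needs exactly 2 arms")
    if tau is None:
        tau = min(t[g == lab].max() for lab in labels)
    res: dict[str, Any] = {"tau": float(tau), "arms": [str(x) for x in labels]}
    rmsts, ses = [], []
    for lab in labels:
        rm, var = _rmst_single(t[g == lab], e[g == lab], tau)
        rmsts.append(rm)
        ses.append(np.sqrt(var) / rm if rm > 0 else np.nan)
    res["rmst"] = {str(lab): rmsts[i] for i, lab in enumerate(labels)}
    ratio = rmsts[1] / rmsts[0]
    se_log = float(np.hypot(ses[0], ses[1]))
    z = stats.norm.ppf(0.975)
    res["ratio"] = float(ratio)
    res["ci_low"] = float(ratio * np.exp(-z * se_log))
    res["ci_high"] = float(ratio * np.exp(z * se_log))
    return res


def stratify_median(scores) -> pd.Series:
    """Median split: strictly above the median = 'high', otherwise 'low'."""
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    if len(s) < 2:
        raise ValidationError("need at least 2 samples to stratify")
    if s.nunique() == 1:
        raise ValidationError("all scores identical: median split undefined")
    med = s.median()
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValidationError("median split produced an empty group")
    return labels


def linear_risk_score(
    expr: ExpressionMatrix,
    coefficients: dict[str, float],
    strict: bool = False,
) -> pd.Series:
    """Coefficient-weighted sum of gene expression per sample.

    Missing genes are skipped and reported via the result's attrs; with
    ``strict=True`` any missing gene is an error (use when only cohorts
    detecting every gene should be scored).
    """
    present = {g: c for g, c in coefficients.items() if g in expr.genes}
    missing = sorted(set(coefficients) - set(present))
    if not present:
        raise ValidationError(f"all coefficient genes missing: {missing}")
    if strict and missing:
        raise ValidationError(f"missing coefficient genes in strict mode: {missing}")
    genes = sorted(present)
    coefs = np.array([present[g] for g in genes])
    risk = pd.Series(
        coefs @ expr.values.loc[genes].to_numpy(dtype=float),
        index=expr.observations,
        name="risk",
    )
    risk.attrs["missing_genes"] = missing
    return risk


def score_to_risk(score: ScoreVector | pd.Series, negate: bool = True) -> pd.Series:
    """Convert a signature score to a risk score (negated by default, since
    higher signature scores track better survival)."""
    s = score.scores if isinstance(score, ScoreVector) else score
    return (-s if negate else s).rename("risk")
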