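"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the data the workflow consumes:

* a single-cell log2 expression matrix with discrete transcriptional states,
  one of which (the "reactive" state) over-expresses a planted marker set;
* a paired-chain clonotype table in which reactive-state cells carry
  multiplied odds of joining expanded clones;
* bulk cohorts in which a standard-normal latent reactivity score drives
  both signature-gene expression and an exponential survival hazard, and a
  response cohort whose responder probability is logistic in the same score.

Every generator is a pure function of its design (identical seed gives
bit-identical output) and returns its ground truth — planted genes, latent
scores, state labels — so downstream recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import CellAnnotation, ClonotypeTable, ExpressionMatrix, ValidationError


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"invalid design field {fieldname!r}: {msg}")


@dataclass
class ScDesign:
    """Design of the synthetic single-cell landscape."""

    n_genes: int = 500
    n_cells: int = 600
    n_states: int = 4
    reactive_state: int = 1
    n_signature_genes: int = 40
    marker_shift: float = 2.0
    dropout_rate: float = 0.1
    base_mean: float = 2.0
    noise_sd: float = 1.0
    n_patients: int = 8
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes >= 2, "n_genes", "need at least 2 genes")
        _check(self.n_cells >= 2, "n_cells", "need at least 2 cells")
        _check(self.n_states >= 2, "n_states", "need at least 2 states")
        _check(
            0 <= self.reactive_state < self.n_states,
            "reactive_state",
            f"must be a state index < {self.n_states}",
        )
        _check(
            0 < self.n_signature_genes < self.n_genes,
            "n_signature_genes",
            "must be positive and below n_genes",
        )
        _check(self.marker_shift >= 0, "marker_shift", "must be >= 0")
        _check(0 <= self.dropout_rate < 1, "dropout_rate", "must lie in [0, 1)")
        _check(self.noise_sd > 0, "noise_sd", "must be positive")
        _check(self.n_patients >= 1, "n_patients", "need at least 1 patient")


@dataclass
class TcrDesign:
    """Design of the synthetic clonotype table.

    ``n_clonotypes`` is the fresh-clonotype pool available per patient;
    ``clonal_enrichment`` multiplies the odds that a reactive-state cell
    joins an already-occupied (hence expanded) clone instead of founding a
    new singleton.
    """

    clonal_enrichment: float = 5.0
    max_clone_size: int = 60
    n_clonotypes: int = 40
    seed: int = 0
    #: Base weight of joining an existing clone relative to a fresh
    #: clonotype; kept well below 1 so that expansion is driven by the
    #: enrichment multiplier and pool exhaustion, not by the base process.
    join_weight: float = 0.1

    def validate(self) -> None:
        _check(self.clonal_enrichment >= 1, "clonal_enrichment", "must be >= 1")
        _check(self.max_clone_size >= 3, "max_clone_size", "must be >= 3")
        _check(self.n_clonotypes >= 1, "n_clonotypes", "must be >= 1")
        _check(self.join_weight > 0, "join_weight", "must be positive")


@dataclass
class CohortDesign:
    """Design of a latent-score-driven bulk cohort.

    The latent reactivity score u ~ N(0, 1) enters expression additively
    (``signature_loading`` log2 units per unit u on every signature gene)
    and survival multiplicatively (hazard ``baseline_hazard *
    exp(latent_effect * u)``). Censoring is an independent exponential.
    """

    n_samples: int = 200
    latent_effect: float = -0.7
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    signature_loading: float = 1.0
    response_logit_slope: float = 2.0
    n_genes: int = 1000
    base_mean: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_samples >= 10, "n_samples", "must be >= 10")
        _check(self.baseline_hazard > 0, "baseline_hazard", "must be positive")
        _check(self.censor_rate >= 0, "censor_rate", "must be >= 0")
        _check(self.n_genes >= 2, "n_genes", "need at least 2 genes")
        _check(self.noise_sd > 0, "noise_sd", "must be positive")


def gen_sc_dataset(design: ScDesign) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Generate a log2 single-cell matrix with one marker-shifted state.

    Exactly ``design.n_signature_genes`` randomly chosen genes gain an
    additive ``marker_shift`` in cells of the reactive state only; all other
    gene/state combinations share the same base distribution. Dropout is
    independent Bernoulli zero-inflation applied after the shift.

    Returns the matrix and a :class:`CellAnnotation` whose ``truth`` dict
    records the planted gene list and the reactive state label.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    cells = [f"cell{i:05d}" for i in range(design.n_cells)]
    states = rng.integers(0, design.n_states, size=design.n_cells)
    patients = rng.integers(0, design.n_patients, size=design.n_cells)

    planted_idx = rng.choice(design.n_genes, size=design.n_signature_genes, replace=False)
    planted = sorted(genes[i] for i in planted_idx)

    x = rng.normal(design.base_mean, design.noise_sd, size=(design.n_genes, design.n_cells))
    reactive_cells = states == design.reactive_state
    shift = np.zeros((design.n_genes, design.n_cells))
    shift[np.ix_(planted_idx, reactive_cells)] = design.marker_shift
    x = x + shift
    x = np.clip(x, 0.0, None)
    if design.dropout_rate > 0:
        x[rng.random(x.shape) < design.dropout_rate] = 0.0

    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=cells), scale="log2")
    ann = CellAnnotation(
        table=pd.DataFrame(
            {
                "state": [f"S{s}" for s in states],
                "patient": [f"P{p}" for p in patients],
            },
            index=pd.Index(cells, name="cell"),
        ),
        truth={
            "planted_genes": planted,
            "reactive_state": f"S{design.reactive_state}",
        },
    )
    return expr, ann


def gen_tcr_table(annotation: CellAnnotation, design: TcrDesign) -> ClonotypeTable:
    """Assign every annotated cell a paired-chain clonotype.

    Within each patient, cells are visited in random order. A cell either
    founds a fresh clonotype (weight proportional to the remaining fresh
    pool) or joins an existing, not-yet-full clone (weight proportional to
    ``join_weight`` times current clone size, multiplied by
    ``clonal_enrichment`` when the cell is in the reactive state). Once the
    fresh pool is exhausted every subsequent cell must join, so pool size
    controls the overall expansion level.
    """
    design.validate()
    if len(annotation.cells) == 0:
        raise ValidationError("empty cell annotation")
    rng = np.random.default_rng(design.seed)
    reactive = annotation.truth.get("reactive_state")

    assign: dict[str, str] = {}
    counter = 0
    for patient, sub in annotation.table.groupby("patient", sort=True):
        order = rng.permutation(len(sub))
        fresh_remaining = design.n_clonotypes
        clones: list[list[str]] = []  # members per open clone
        clone_ids: list[str] = []
        for pos in order:
            cell = sub.index[pos]
            is_reactive = reactive is not None and sub.iloc[pos]["state"] == reactive
            open_idx = [i for i, m in enumerate(clones) if len(m) < design.max_clone_size]
            w_join = np.array(
                [design.join_weight * len(clones[i]) for i in open_idx], dtype=float
            )
            if is_reactive:
                w_join = w_join * design.clonal_enrichment
            w_new = float(fresh_remaining)
            total = w_new + w_join.sum()
            if total <= 0:  # full pool and all clones capped: reopen largest
                open_idx = list(range(len(clones)))
                w_join = np.ones(len(clones))
                w_new, total = 0.0, float(len(clones))
            if rng.random() < w_new / total:
                cid = f"TRA:{counter}|TRB:{counter}"
                counter += 1
                fresh_remaining -= 1
                clones.append([cell])
                clone_ids.append(cid)
                assign[cell] = cid
            else:
                j = open_idx[rng.choice(len(open_idx), p=w_join / w_join.sum())]
                clones[j].append(cell)
                assign[cell] = clone_ids[j]

    table = pd.DataFrame(
        {
            "sample": annotation.table["patient"],
            "clonotype": [assign[c] for c in annotation.table.index],
        },
        index=annotation.table.index,
    )
    sizes = table.groupby("clonotype")["clonotype"].transform("size")
    table["clone_size"] = sizes.astype(int)
    table["state"] = annotation.table["state"]
    return ClonotypeTable(table=table, scope="global")


def _cohort_expression(
    design: CohortDesign, signature_genes: list[str], u: np.ndarray, rng: np.random.Generator
) -> ExpressionMatrix:
    n = design.n_samples
    k = len(signature_genes)
    n_bg = max(design.n_genes - k, 0)
    bg_genes = [f"BG{i:05d}" for i in range(n_bg)]
    samples = [f"sample{i:04d}" for i in range(n)]
    sig = design.base_mean + design.signature_loading * u[None, :] + rng.normal(
        0, design.noise_sd, size=(k, n)
    )
    bg = design.base_mean + rng.normal(0, design.noise_sd, size=(n_bg, n))
    values = pd.DataFrame(
        np.vstack([sig, bg]), index=signature_genes + bg_genes, columns=samples
    )
    return ExpressionMatrix(values, scale="log2")


def gen_bulk_cohort(
    design: CohortDesign, signature
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Simulate a bulk cohort whose latent score drives expression and hazard.

    Survival times are exponential with hazard ``baseline_hazard *
    exp(latent_effect * u)``; censoring is an independent exponential with
    rate ``censor_rate`` (no censoring when the rate is 0). Returns the
    expression matrix, a survival table (time, event) and the latent scores.
    """
    design.validate()
    genes = list(signature.genes) if hasattr(signature, "genes") else list(signature)
    if len(genes) == 0:
        raise ValidationError("empty signature")
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    u = rng.standard_normal(n)
    expr = _cohort_expression(design, genes, u, rng)

    hazard = design.baseline_hazard * np.exp(design.latent_effect * u)
    event_time = rng.exponential(1.0 / hazard)
    if design.censor_rate > 0:
        censor_time = rng.exponential(1.0 / design.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(expr.observations, name="sample")
    )
    latent = pd.Series(u, index=expr.observations, name="latent")
    return expr, surv, latent


def gen_response_cohort(
    design: CohortDesign, signature
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Simulate a response cohort: P(responder | u) = logistic(slope * u)."""
    design.validate()
    genes = list(signature.genes) if hasattr(signature, "genes") else list(signature)
    if len(genes) == 0:
        raise ValidationError("empty signature")
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    u = rng.standard_normal(n)
    expr = _cohort_expression(design, genes, u, rng)
    p = expit(design.response_logit_slope * u)
    labels = pd.Series(
        (rng.random(n) < p).astype(int), index=expr.observations, name="responder"
    )
    latent = pd.Series(u, index=expr.observations, name="latent")
    return expr, labels, latent
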