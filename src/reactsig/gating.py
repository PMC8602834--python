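"""CD8 gating and protocol-specific gene/cell filters.

Gating selects CD8-positive, CD4-negative T cells on log-normalized
expression: mean of the CD8 genes strictly above ``cd8_threshold`` and CD4
strictly below ``cd4_threshold``. Filtering applies one of two protocol
profiles before signature work: a full-length (Smart-seq2 / bulk-like)
profile keeping genes by mean expression and detection rate, and a
droplet-style (MARS-seq, raw counts) profile that first drops cells by
expressed-gene count and then keeps genes by detection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class GatingConfig:
    """Thresholded CD8+/CD4- gate; inequalities are strict on both sides."""

    cd8_genes: list[str] = field(default_factory=lambda: ["CD8A", "CD8B"])
    cd4_gene: str = "CD4"
    cd8_threshold: float = 2.0
    cd4_threshold: float = 2.0

    def validate(self) -> None:
        if not self.cd8_genes:
            raise ValidationError("cd8_genes must be non-empty")
        if not np.isfinite([self.cd8_threshold, self.cd4_threshold]).all():
            raise ValidationError("gate thresholds must be finite")


_PROFILES = {
    "smartseq2_bulklike": dict(min_gene_mean=0.5, min_gene_detect_rate=0.1),
    "marsseq": dict(min_gene_detect_rate=0.01, cell_min_genes=500, cell_max_genes=3000),
}


@dataclass
class FilterProfile:
    """Named gene/cell filter profile.

    ``smartseq2_bulklike``: keep genes with mean > ``min_gene_mean`` and
    detection rate > ``min_gene_detect_rate``.
    ``marsseq``: drop cells with expressed-gene count outside
    [``cell_min_genes``, ``cell_max_genes``] (inclusive), then keep genes
    with detection rate > ``min_gene_detect_rate`` on surviving cells.
    "Expressed" means strictly positive on the declared scale.
    """

    name: str = "smartseq2_bulklike"
    min_gene_mean: float | None = None
    min_gene_detect_rate: float | None = None
    cell_min_genes: int | None = None
    cell_max_genes: int | None = None

    def __post_init__(self) -> None:
        if self.name not in _PROFILES:
            raise ValidationError(
                f"unknown filter profile {self.name!r}; expected one of {sorted(_PROFILES)}"
            )
        for key, default in _PROFILES[self.name].items():
            if getattr(self, key) is None:
                setattr(self, key, default)
        if not (0.0 <= self.min_gene_detect_rate <= 1.0):
            raise ValidationError("min_gene_detect_rate must lie in [0, 1]")
        if self.name == "marsseq" and not (self.cell_min_genes < self.cell_max_genes):
            raise ValidationError("cell_min_genes must be below cell_max_genes")


def gate_cd8(expr: ExpressionMatrix, cfg: GatingConfig | None = None) -> list[str]:
    """Return ids of cells passing the CD8+/CD4- gate, in input order.

    A cell is retained iff the mean of the available CD8 genes is strictly
    greater than ``cd8_threshold`` and its CD4 expression is strictly less
    than ``cd4_threshold``. Missing CD8 genes are tolerated as long as at
    least one is present; a missing CD4 gene is an error.
    """
    cfg = cfg or GatingConfig()
    cfg.validate()
    present_cd8 = [g for g in cfg.cd8_genes if g in expr.genes]
    if not present_cd8:
        raise ValidationError(f"none of the CD8 genes {cfg.cd8_genes} present in matrix")
    if cfg.cd4_gene not in expr.genes:
        raise ValidationError(f"CD4 gene {cfg.cd4_gene!r} absent from matrix")
    cd8_mean = expr.values.loc[present_cd8].mean(axis=0)
    cd4 = expr.values.loc[cfg.cd4_gene]
    keep = (cd8_mean > cfg.cd8_threshold) & (cd4 < cfg.cd4_threshold)
    return [c for c in expr.observations if keep[c]]


def filter_genes_cells(expr: ExpressionMatrix, profile: FilterProfile) -> ExpressionMatrix:
    """Apply a protocol filter profile; see :class:`FilterProfile`."""
    values = expr.values
    if values.empty:
        raise ValidationError("empty expression matrix")
    if profile.name == "marsseq":
        if expr.scale != "counts":
            raise ValidationError("marsseq profile expects a raw-count matrix")
        n_expressed = (values > 0).sum(axis=0)
        cell_keep = (n_expressed >= profile.cell_min_genes) & (
            n_expressed <= profile.cell_max_genes
        )
        values = values.loc[:, cell_keep]
        if values.shape[1] == 0:
            raise ValidationError(
                "all cells removed by expressed-gene-count bounds; review thresholds"
            )
        detect = (values > 0).mean(axis=1)
        gene_keep = detect > profile.min_gene_detect_rate
    else:
        detect = (values > 0).mean(axis=1)
        gene_keep = (values.mean(axis=1) > profile.min_gene_mean) & (
            detect > profile.min_gene_detect_rate
        )
    values = values.loc[gene_keep]
    if values.shape[0] == 0:
        raise ValidationError("all genes removed by filter; review thresholds")
    return ExpressionMatrix(values.copy(), expr.scale)
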