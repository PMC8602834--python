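"""Core in-memory containers shared across the pipeline.

Expression data travels as a gene-by-observation matrix with an explicitly
declared scale (``log2``, ``tpm`` or ``counts``); downstream operations that
are scale-sensitive refuse matrices whose scale they cannot interpret.
Signatures, scores, survival records and clonotype assignments are thin
wrappers around pandas objects so that every stage stays inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

#: Expression scales a matrix may declare.
VALID_SCALES = ("log2", "tpm", "counts")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Genes x observations expression matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are observation (cell or
        sample) ids.
    scale
        One of ``log2`` (log-normalized), ``tpm`` or ``counts``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.scale not in VALID_SCALES:
            raise ValidationError(
                f"undeclared or unknown expression scale {self.scale!r}; "
                f"expected one of {VALID_SCALES}"
            )
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def observations(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.scale)

    def subset_observations(self, obs: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(obs)], self.scale)


@dataclass
class CellAnnotation:
    """Per-cell metadata: transcriptional state and patient of origin.

    ``truth`` carries generator ground truth (planted signature genes,
    reactive state index) when the annotation comes from simulation.
    """

    table: pd.DataFrame  # index: cell id; columns: state, patient
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"state", "patient"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"cell annotation missing columns {sorted(missing)}")

    @property
    def cells(self) -> pd.Index:
        return self.table.index

    def states(self) -> pd.Series:
        return self.table["state"]


@dataclass
class GeneSignature:
    """Ordered gene list with per-gene discrimination AUCs.

    Genes are sorted by AUC descending with lexicographic tie-break.
    Optional per-gene coefficients support linear risk scores.
    """

    genes: list[str]
    auc: dict[str, float] = field(default_factory=dict)
    k: int | None = None
    coefficients: dict[str, float] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("signature genes must be unique")
        for g, a in self.auc.items():
            if not (0.0 <= a <= 1.0):
                raise ValidationError(f"AUC for {g} outside [0, 1]: {a}")

    def __len__(self) -> int:
        return len(self.genes)

    def drop(self, gene: str) -> "GeneSignature":
        if gene not in self.genes:
            raise KeyError(gene)
        remaining = [g for g in self.genes if g != gene]
        return GeneSignature(
            genes=remaining,
            auc={g: a for g, a in self.auc.items() if g != gene},
            k=self.k,
            coefficients=None
            if self.coefficients is None
            else {g: c for g, c in self.coefficients.items() if g != gene},
            provenance=dict(self.provenance),
        )


@dataclass
class ScoreVector:
    """Per-observation signature score tagged with the producing method."""

    scores: pd.Series
    method: str
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"non-finite scores produced by {self.method}")

    @property
    def observations(self) -> pd.Index:
        return self.scores.index


def validate_survival(table: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table: positive finite times, 0/1 event flags.

    Expected columns: ``time`` and ``event``; the index holds sample ids.
    Extra columns are treated as covariates and passed through.
    """
    missing = {"time", "event"} - set(table.columns)
    if missing:
        raise ValidationError(f"survival table missing columns {sorted(missing)}")
    t = np.asarray(table["time"], dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("survival times must be positive and finite")
    ev = np.asarray(table["event"])
    if not np.isin(ev, [0, 1]).all():
        raise ValidationError("event flags must be 0 or 1")
    return table


@dataclass
class ClonotypeTable:
    """Per-cell clonotype assignment with clone sizes and clonality class.

    ``table`` is indexed by cell id with columns ``sample``, ``clonotype``,
    ``clone_size`` and (after classification) ``clonality_class``.
    """

    table: pd.DataFrame
    scope: str = "global"
    n_rejected: int = 0

    def __post_init__(self) -> None:
        required = {"sample", "clonotype", "clone_size"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"clonotype table missing columns {sorted(missing)}")
        if (self.table["clone_size"] < 1).any():
            raise ValidationError("clone sizes must be >= 1")

    @property
    def cells(self) -> pd.Index:
        return self.table.index


def as_mapping(obj: Any) -> Mapping[str, Any]:
    """Return a dict view of a dataclass-like config for provenance records."""
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"cannot snapshot config of type {type(obj)!r}")
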