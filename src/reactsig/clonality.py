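"""TCR clonotype construction, expansion classes and rarefied diversity.

A clonotype is an exact paired alpha-beta chain string; its clone size is
the number of cells sharing it within the chosen scope (per sample or
global). Cells are classed by clone size: 1 = unique, 2 = repeated,
>= ``clonal_min_size`` (default 3) = clonal. Repertoire diversity per
sample is the Shannon entropy of clonotype frequencies, rarefied by
repeated downsampling to a common depth so that samples of different
repertoire sizes are comparable. Note the quantity reported is entropy
(higher = more diverse); conventional "clonality" is one minus normalized
entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClonotypeTable, ValidationError


@dataclass
class ClonalityConfig:
    """Expansion threshold and rarefaction settings.

    depth
        Subsampling depth; ``None`` means the minimum repertoire size across
        included samples. Samples below the depth are reported missing, not
        extrapolated.
    """

    clonal_min_size: int = 3
    depth: int | None = None
    n_replicates: int = 1000
    log_base: float | None = None  # natural log when None
    seed: int = 0

    def validate(self) -> None:
        if self.clonal_min_size < 2:
            raise ValidationError("clonal_min_size must be >= 2")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.depth is not None and self.depth < 1:
            raise ValidationError("depth must be >= 1")


def build_clonotypes(records: pd.DataFrame, scope: str = "per-sample") -> ClonotypeTable:
    """Build a clonotype table from per-cell chain records.

    ``records`` must have columns ``cell_id``, ``sample_id``, ``alpha`` and
    ``beta``. Records with a missing chain are rejected (counted in
    ``n_rejected``). Clone sizes are counted within each sample for
    ``per-sample`` scope, or across the whole table for ``global``.
    """
    if scope not in ("per-sample", "global"):
        raise ValidationError(f"unknown scope {scope!r}")
    required = {"cell_id", "sample_id", "alpha", "beta"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns {sorted(missing)}")
    chains = records[["alpha", "beta"]].astype(object)
    bad = (
        chains.isna().any(axis=1)
        | (chains["alpha"].astype(str).str.len() == 0)
        | (chains["beta"].astype(str).str.len() == 0)
    )
    kept = records.loc[~bad]
    if kept.empty:
        raise ValidationError("no record with both chains present")
    table = pd.DataFrame(
        {
            "sample": kept["sample_id"].to_numpy(),
            "clonotype": (kept["alpha"].astype(str) + "|" + kept["beta"].astype(str)).to_numpy(),
        },
        index=pd.Index(kept["cell_id"], name="cell"),
    )
    if scope == "per-sample":
        sizes = table.groupby(["sample", "clonotype"])["clonotype"].transform("size")
    else:
        sizes = table.groupby("clonotype")["clonotype"].transform("size")
    table["clone_size"] = sizes.astype(int)
    return ClonotypeTable(table=table, scope=scope, n_rejected=int(bad.sum()))


def classify_clonality(table: ClonotypeTable, cfg: ClonalityConfig | None = None) -> ClonotypeTable:
    """Label each cell unique / repeated / clonal by its clone size."""
    cfg = cfg or ClonalityConfig()
    cfg.validate()
    sizes = table.table["clone_size"]
    cls = np.where(
        sizes >= cfg.clonal_min_size, "clonal", np.where(sizes >= 2, "repeated", "unique")
    )
    out = table.table.copy()
    out["clonality_class"] = cls
    return ClonotypeTable(table=out, scope=table.scope, n_rejected=table.n_rejected)


def shannon_entropy(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy of a count vector (natural log by default)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def rarefied_entropy(
    table: ClonotypeTable, cfg: ClonalityConfig | None = None
) -> pd.DataFrame:
    """Downsampling-rarefied Shannon entropy per sample.

    For each sample with at least ``depth`` cells, draws ``n_replicates``
    seeded subsamples of ``depth`` cells without replacement and reports the
    mean and SD of the subsample entropies. Samples below the depth get NaN
    with a reason. Depth defaults to the minimum repertoire size across
    samples.
    """
    cfg = cfg or ClonalityConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    groups = dict(tuple(table.table.groupby("sample")["clonotype"]))
    if not groups:
        raise ValidationError("empty clonotype table")
    sizes = {s: len(v) for s, v in groups.items()}
    depth = cfg.depth if cfg.depth is not None else min(sizes.values())

    rows = []
    for sample in sorted(groups):
        clonos = groups[sample].to_numpy()
        m = len(clonos)
        if m < depth:
            rows.append(
                dict(sample=sample, n_cells=m, depth=depth, entropy_mean=np.nan,
                     entropy_sd=np.nan, reason=f"repertoire size {m} below depth {depth}")
            )
            continue
        if m == depth:
            h = shannon_entropy(pd.Series(clonos).value_counts().to_numpy(), cfg.log_base)
            rows.append(
                dict(sample=sample, n_cells=m, depth=depth, entropy_mean=h,
                     entropy_sd=0.0, reason="")
            )
            continue
        codes = pd.factorize(clonos)[0]
        n_codes = codes.max() + 1
        hs = np.empty(cfg.n_replicates)
        for b in range(cfg.n_replicates):
            sub = rng.choice(codes, size=depth, replace=False)
            hs[b] = shannon_entropy(np.bincount(sub, minlength=n_codes), cfg.log_base)
        rows.append(
            dict(sample=sample, n_cells=m, depth=depth, entropy_mean=float(hs.mean()),
                 entropy_sd=float(hs.std(ddof=0)), reason="")
        )
    out = pd.DataFrame(rows).set_index("sample")
    out.attrs.update({"depth": depth, "n_replicates": cfg.n_replicates, "seed": cfg.seed})
    return out


def clonality_composition(table: ClonotypeTable, by: str | None = None) -> pd.DataFrame:
    """Cell counts per clonality class, overall or grouped by a column."""
    if "clonality_class" not in table.table.columns:
        raise ValidationError("classify_clonality must run first")
    t = table.table
    classes = ["unique", "repeated", "clonal"]
    if by is None:
        counts = t["clonality_class"].value_counts().reindex(classes, fill_value=0)
        return counts.to_frame("n_cells").T
    out = (
        t.groupby(by)["clonality_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=classes, fill_value=0)
    )
    return out
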