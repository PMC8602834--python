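"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as dense TSV/CSV (genes in rows, header row of
observation ids) or as MatrixMarket triplets with sidecar row/column name
files; gene sets as GMT; annotations, clonotypes and survival tables as
TSV with header. All outputs are UTF-8 and tab-separated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionMatrix, GeneSignature, ValidationError


def read_expression(
    path: str | Path,
    scale: str,
    rows: str | Path | None = None,
    cols: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or MTX (+ row/col name files)."""
    path = Path(path)
    if path.suffix == ".mtx":
        if rows is None or cols is None:
            raise ValidationError("MTX input needs row and column name files")
        mat = spio.mmread(path)
        genes = Path(rows).read_text().split()
        obs = Path(cols).read_text().split()
        values = pd.DataFrame(np.asarray(mat.todense()), index=genes, columns=obs)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        values = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(values, scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path, mtx: bool = False) -> None:
    path = Path(path)
    if mtx:
        spio.mmwrite(path.with_suffix(".mtx"), sparse.coo_matrix(expr.values.to_numpy()))
        path.with_suffix(".rows.txt").write_text("\n".join(map(str, expr.genes)) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(map(str, expr.observations)) + "\n")
    else:
        expr.values.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValidationError("empty GMT file")
    return sets


def write_gmt(signature: GeneSignature, path: str | Path, name: str = "signature") -> None:
    desc = signature.provenance.get("source_cluster") or "reactsig"
    line = "\t".join([name, str(desc)] + list(signature.genes))
    Path(path).write_text(line + "\n")


def signature_from_gmt(path: str | Path, name: str | None = None) -> GeneSignature:
    sets = read_gmt(path)
    if name is None:
        name = next(iter(sets))
    if name not in sets:
        raise ValidationError(f"gene set {name!r} not in GMT file")
    return GeneSignature(genes=sets[name], provenance={"source": str(path), "set": name})


def write_signature_table(signature: GeneSignature, path: str | Path) -> None:
    """TSV companion to the GMT record: gene, AUC and coefficient columns."""
    rows = {
        "gene": list(signature.genes),
        "auc": [signature.auc.get(g, np.nan) for g in signature.genes],
    }
    if signature.coefficients:
        rows["coefficient"] = [signature.coefficients.get(g, np.nan) for g in signature.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
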