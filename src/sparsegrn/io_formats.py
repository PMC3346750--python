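"""Readers/writers for the external formats and median imputation.

Internal orientation is frozen as samples x features; GCT (features x
samples) is transposed at the boundary. Missing values are an empty cell or
"NA" (case-insensitive). Malformed input is rejected with a diagnostic that
names the offending line rather than silently coerced.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import CategoryCollection
from .model_core import ExpressionDataset, ModelParameters

__all__ = [
    "read_expression_matrix",
    "write_expression_tsv",
    "median_impute",
    "split_tf_genes",
    "read_tf_list",
    "read_gmt",
    "write_gmt",
    "save_model",
    "load_model",
]

MISSING_TOKENS = {"", "na", "nan"}
MODEL_FORMAT_VERSION = "1"


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def _parse_table(lines: list[str], path, start_line: int = 1) -> pd.DataFrame:
    """Parse header + rows of a tab-delimited numeric table (first column =
    row ids), reporting 1-based line numbers on malformed content."""
    if not lines:
        raise ValueError(f"{path}: empty table")
    header = lines[0].rstrip("\r\n").split("\t")
    col_ids = [c.strip() for c in header[1:]]
    if len(set(col_ids)) != len(col_ids):
        raise ValueError(f"{path}: duplicate column identifiers in header")
    n_cols = len(col_ids)
    row_ids: list[str] = []
    values: list[list[float]] = []
    for offset, raw in enumerate(lines[1:], start=start_line + 1):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != n_cols + 1:
            raise ValueError(
                f"{path}: line {offset}: expected {n_cols + 1} fields, got {len(cells)}"
            )
        row_ids.append(cells[0].strip())
        row: list[float] = []
        for j, cell in enumerate(cells[1:]):
            if _is_missing(cell):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: line {offset}: non-numeric value {cell!r} "
                    f"in column {col_ids[j]!r}"
                ) from None
        values.append(row)
    if len(set(row_ids)) != len(row_ids):
        raise ValueError(f"{path}: duplicate row identifiers")
    return pd.DataFrame(np.asarray(values, dtype=float), index=row_ids, columns=col_ids)


def read_expression_matrix(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a TSV or GCT expression matrix as samples x features.

    TSV: header row of feature ids, first column sample ids. GCT 1.2:
    '#1.2' line, dimension line, then a features x samples table with Name
    and Description columns — transposed on read and validated against the
    dimension line.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gct" if path.suffix.lower() == ".gct" else "tsv"
    lines = path.read_text().splitlines()
    if dialect == "tsv":
        return _parse_table(lines, path)
    if dialect != "gct":
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(lines) < 3 or not lines[0].startswith("#1.2"):
        raise ValueError(f"{path}: not a GCT 1.2 file (missing '#1.2' header)")
    dims = lines[1].split("\t")
    try:
        n_features, n_samples = int(dims[0]), int(dims[1])
    except (IndexError, ValueError):
        raise ValueError(f"{path}: line 2: malformed GCT dimension line") from None
    header = lines[2].rstrip("\r\n").split("\t")
    if len(header) < 3 or header[0] != "Name":
        raise ValueError(f"{path}: line 3: GCT header must start with Name\tDescription")
    sample_ids = [c.strip() for c in header[2:]]
    if len(sample_ids) != n_samples:
        raise ValueError(
            f"{path}: dimension line declares {n_samples} samples, "
            f"header has {len(sample_ids)}"
        )
    # Drop the Description column, then reuse the TSV parser.
    body = ["\t".join([header[0]] + sample_ids)]
    for i, raw in enumerate(lines[3:], start=4):
        if not raw.strip():
            continue
        cells = raw.rstrip("\r\n").split("\t")
        if len(cells) != n_samples + 2:
            raise ValueError(
                f"{path}: line {i}: expected {n_samples + 2} fields, got {len(cells)}"
            )
        body.append("\t".join([cells[0]] + cells[2:]))
    frame = _parse_table(body, path, start_line=3)
    if frame.shape[0] != n_features:
        raise ValueError(
            f"{path}: dimension line declares {n_features} features, "
            f"table has {frame.shape[0]}"
        )
    return frame.T  # features x samples -> samples x features


def write_expression_tsv(frame: pd.DataFrame, path) -> None:
    """Write samples x features TSV (empty cell for missing values)."""
    frame.to_csv(path, sep="\t", na_rep="", float_format="%.12g")


def median_impute(frame: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the per-feature median of observed values."""
    out = frame.copy()
    all_missing = out.isna().all(axis=0)
    if all_missing.any():
        bad = out.columns[all_missing][0]
        raise ValueError(f"feature {bad!r} has no observed values; cannot impute")
    return out.fillna(out.median(axis=0))


def split_tf_genes(frame: pd.DataFrame, tf_ids: list[str]) -> ExpressionDataset:
    """Partition feature columns into TF matrix R and gene matrix X.

    TFs absent from the matrix are logged as a warning and skipped; the
    disjointness of the two identifier sets then holds by construction.
    """
    present = [t for t in tf_ids if t in frame.columns]
    absent = [t for t in tf_ids if t not in frame.columns]
    if absent:
        warnings.warn(
            f"{len(absent)} listed TFs absent from the expression matrix "
            f"(first few: {absent[:5]})",
            stacklevel=2,
        )
    if not present:
        warnings.warn("no listed TF present in the matrix; d = 0", stacklevel=2)
    present_set = set(present)
    gene_cols = [c for c in frame.columns if c not in present_set]
    return ExpressionDataset(
        X=frame[gene_cols].to_numpy(dtype=float),
        R=frame[present].to_numpy(dtype=float),
        gene_ids=gene_cols,
        tf_ids=present,
        sample_ids=[str(s) for s in frame.index],
    )


def read_tf_list(path) -> list[str]:
    """Plain-text TF list: one identifier per line, '#' comments allowed."""
    ids: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        ids.append(line)
    return ids


def read_gmt(path) -> CategoryCollection:
    """GSEA GMT: name <tab> description <tab> member genes...

    Tolerant of trailing tabs and CRLF line endings; the universe is the
    union of all members.
    """
    cats: dict[str, frozenset[str]] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {i}: GMT rows need name, description, members")
        name = fields[0].strip()
        members = frozenset(g.strip() for g in fields[2:] if g.strip())
        if name in cats:
            raise ValueError(f"{path}: line {i}: duplicate category {name!r}")
        cats[name] = members
    universe = frozenset().union(*cats.values()) if cats else frozenset()
    return CategoryCollection(categories=cats, universe=universe)


def write_gmt(collection: CategoryCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.categories):
            members = sorted(collection.categories[name])
            fh.write("\t".join([name, "synthetic"] + members) + "\n")


def save_model(params: ModelParameters, path, metadata: dict | None = None) -> None:
    """Single self-describing archive of the fitted model (npz + version)."""
    meta = dict(metadata or {})
    meta.setdefault("format_version", MODEL_FORMAT_VERSION)
    np.savez(
        path,
        W=params.W,
        Lambda=params.Lambda,
        mu=params.mu,
        sigma2=np.asarray(params.sigma2),
        gene_ids=np.asarray(params.gene_ids or [], dtype=object),
        tf_ids=np.asarray(params.tf_ids or [], dtype=object),
        meta=json.dumps(meta),
    )


def load_model(path) -> tuple[ModelParameters, dict]:
    with np.load(path, allow_pickle=True) as arc:
        meta = json.loads(str(arc["meta"]))
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model archive version {meta.get('format_version')!r}"
            )
        gene_ids = [str(g) for g in arc["gene_ids"]] or None
        tf_ids = [str(t) for t in arc["tf_ids"]]
        params = ModelParameters(
            W=arc["W"],
            Lambda=arc["Lambda"],
            mu=arc["mu"],
            sigma2=float(arc["sigma2"]),
            gene_ids=gene_ids,
            tf_ids=tf_ids if tf_ids else None,
        )
    return params, meta
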