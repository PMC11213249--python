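"""Readers and writers for the standard formats the pipeline touches.

Count matrices are represented as :class:`pandas.DataFrame` with gene ids on
the index and cell/sample ids on the columns (genes x columns orientation, as
on disk).  All readers validate rather than coerce: duplicate ids, negative
entries and dimension mismatches raise :class:`FormatError`.

Matrix Market files are 1-based on disk (the format's standard); indices are
converted to 0-based positions in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_counts",
    "write_counts",
    "read_metadata",
    "read_edges",
    "write_edges",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_ids(ids, what: str, path) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()][0]
        raise FormatError(f"{path}: duplicate {what} id {dup!r}")


def validate_counts(values: pd.DataFrame, path="<memory>") -> pd.DataFrame:
    _check_ids(values.index, "gene", path)
    _check_ids(values.columns, "column", path)
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count matrix")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative entry at gene {values.index[i]!r}, "
            f"column {values.columns[j]!r}"
        )
    return values


def read_counts(
    path,
    format: str | None = None,
    genes_path=None,
    columns_path=None,
) -> pd.DataFrame:
    """Read a genes x columns count matrix from dense TSV or Matrix Market.

    For ``mtx`` input the gene and column id files default to ``genes.tsv``
    and ``cells.tsv`` next to the matrix file (one id per line, first field).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return validate_counts(df, path)
    if format != "mtx":
        raise ValueError(f"unknown count format {format!r}")
    genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
    columns_path = Path(columns_path) if columns_path else path.parent / "cells.tsv"
    for p in (path, genes_path, columns_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(path)  # converts 1-based triplets to 0-based
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cols = pd.read_csv(columns_path, sep="\t", header=None)[0].astype(str)
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(cols)):
        raise FormatError(
            f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]} but id files list "
            f"{len(genes)} genes and {len(cols)} columns"
        )
    df = pd.DataFrame(mat.toarray(), index=genes.tolist(), columns=cols.tolist())
    return validate_counts(df, path)


def write_counts(values: pd.DataFrame, path, format: str | None = None) -> None:
    """Write a count matrix as dense TSV or Matrix Market triplet + id files."""
    path = Path(path)
    validate_counts(values, "<output>")
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        values.to_csv(path, sep="\t")
        return
    if format != "mtx":
        raise ValueError(f"unknown count format {format!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(values.to_numpy())
    scipy.io.mmwrite(path, sparse)
    pd.Series(values.index).to_csv(
        path.parent / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(values.columns).to_csv(
        path.parent / "cells.tsv", sep="\t", header=False, index=False
    )


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV indexed by sample id.

    Recognized columns: time_hours, age_days, replicate, stage, and any number
    of named numeric traits (pseudotime, biomass, leaf_area, ...).
    """
    df = pd.read_csv(path, index_col=0)
    _check_ids(df.index, "sample", path)
    return df


def read_edges(path) -> pd.DataFrame:
    """Read a directed edge list TSV (source<TAB>target, no header required).

    Duplicate edges are collapsed (count logged); self-loops are retained and
    flagged in the ``self_loop`` column.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs >=2 columns")
    if {"source", "target"} <= set(df.iloc[0].tolist()):
        df = df.iloc[1:].reset_index(drop=True)
    edges = df.iloc[:, :2].copy()
    edges.columns = ["source", "target"]
    bad = edges.isna().any(axis=1)
    if bad.any():
        raise FormatError(f"{path}: malformed line {int(bad.idxmax()) + 1}")
    n_dup = int(edges.duplicated().sum())
    if n_dup:
        logger.info("%s: collapsed %d duplicate edges", path, n_dup)
    edges = edges.drop_duplicates(ignore_index=True)
    edges["self_loop"] = edges["source"] == edges["target"]
    n_loops = int(edges["self_loop"].sum())
    if n_loops:
        logger.info("%s: %d self-loops retained", path, n_loops)
    edges.attrs["n_duplicates_collapsed"] = n_dup
    return edges


def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["source", "target"]].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene-set annotations: term, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs >=3 fields")
            term = fields[0]
            if term in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate term {term!r}")
            sets[term] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, description, *genes]) + "\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table as TSV with deterministic column order and
    floats at 6 significant digits."""
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def report_id_overlap(a, b, what: str = "gene") -> pd.Index:
    """Log ids present in one input but not the other; return the shared set
    in the order of ``a``."""
    a, b = pd.Index(a), pd.Index(b)
    only_a, only_b = a.difference(b), b.difference(a)
    if len(only_a) or len(only_b):
        logger.info(
            "%s id overlap: %d shared, %d only in first, %d only in second",
            what, len(a.intersection(b)), len(only_a), len(only_b),
        )
    return a[a.isin(b)]
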