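"""Temporal and trait profiling of cell-type activity.

Fraction tables become activity heatmap inputs by replicate averaging and
per-type z-scoring; trait relationships use Spearman rank correlation; gene
sets are profiled across reference clusters by z-scored mean expression.

Conventions (stated because the field leaves them implicit): standard
deviations are the sample (n-1) form throughout; a constant column z-scores
to all zeros; z-scoring happens after any replicate averaging.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .signature import _cp10k

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_by_celltype",
    "average_replicates",
    "trait_correlation",
    "geneset_cluster_profile",
    "peak_time",
]


def _zscore_frame(df: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """z = (x - mean) / sd with n-1 sd along ``axis``; constant slices -> 0."""
    if axis == 1:
        return _zscore_frame(df.T).T
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    constant = (df.max(axis=0) - df.min(axis=0)) == 0  # robust to fp mean error
    sd = sd.where(~constant & (sd > 0), np.inf)
    z = (df - mu).div(sd, axis=1)
    return z.fillna(0.0)


def zscore_by_celltype(fractions: pd.DataFrame) -> pd.DataFrame:
    """Per-type column z-score of a samples x types fraction table."""
    if len(fractions) < 2:
        raise ValueError("need at least 2 samples to z-score")
    return _zscore_frame(fractions, axis=0)


def average_replicates(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    time_column: str = "time_hours",
    zscore: bool = True,
) -> pd.DataFrame:
    """Mean fraction per (timepoint, type) across replicates, then per-type
    z-scores.  Returns a timepoints x types table indexed by the time value."""
    if time_column not in metadata.columns:
        raise ValueError(f"metadata lacks column {time_column!r}")
    shared = fractions.index.intersection(metadata.index)
    missing = metadata.index.difference(fractions.index)
    if len(missing):
        logger.warning("%d metadata samples have no fractions; omitted", len(missing))
    times = metadata.loc[shared, time_column]
    grouped = fractions.loc[shared].groupby(times.to_numpy()).mean()
    grouped.index.name = time_column
    grouped = grouped.sort_index()
    return _zscore_frame(grouped, axis=0) if zscore else grouped


def trait_correlation(
    fractions: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation (average-rank ties, two-sided p) between each
    cell type's fraction and each trait across plants.  Constant traits give
    missing values.  Returns a types x traits table of (rho, p) columns."""
    shared = fractions.index.intersection(traits.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 samples with trait values")
    F, T = fractions.loc[shared], traits.loc[shared]
    out = {}
    for trait in T.columns:
        tvals = T[trait].to_numpy(dtype=float)
        for typ in F.columns:
            x = F[typ].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(tvals))
            if ok.sum() < 4 or np.std(tvals[ok]) == 0 or np.std(x[ok]) == 0:
                out[(typ, trait)] = (np.nan, np.nan)
            else:
                rho, p = scipy.stats.spearmanr(x[ok], tvals[ok])
                out[(typ, trait)] = (float(rho), float(p))
    table = pd.DataFrame(out, index=["rho", "p"]).T
    table.index = pd.MultiIndex.from_tuples(table.index, names=["cell_type", "trait"])
    return table


def geneset_cluster_profile(
    sc_counts: pd.DataFrame, labels: pd.Series, gene_set
) -> pd.DataFrame:
    """Per cluster, the mean depth-normalized expression of each gene in the
    set, z-scored across clusters per gene.  Genes absent from the reference
    are dropped and logged.  Returns clusters x genes."""
    gene_set = pd.Index(gene_set)
    present = gene_set.intersection(sc_counts.index)
    absent = gene_set.difference(sc_counts.index)
    if len(absent):
        logger.warning("gene set: %d genes absent from reference: %s",
                       len(absent), list(absent[:10]))
    if len(present) == 0:
        raise ValueError("no gene-set genes present in the reference")
    labels = pd.Series(labels).loc[sc_counts.columns]
    norm = pd.DataFrame(
        _cp10k(sc_counts.to_numpy(dtype=float)),
        index=sc_counts.index, columns=sc_counts.columns,
    )
    means = norm.loc[present].T.groupby(labels.to_numpy()).mean()  # clusters x genes
    means.index.name = "cluster"
    return _zscore_frame(means, axis=0)


def peak_time(activity: pd.DataFrame) -> pd.Series:
    """Per type, the time index of the trajectory maximum (ties -> earliest).
    Expects a timepoints x types table with an ordered time index."""
    ordered = activity.sort_index()
    return pd.Series(
        {typ: ordered[typ].idxmax() for typ in ordered.columns}, name="peak_time"
    )
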