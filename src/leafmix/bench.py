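"""Simulated bulk RNA-seq benchmark of deconvolution accuracy.

Cells are split 75/25 per type; the signature is built on the training cells
and pseudobulks are assembled from the held-out test cells:

* single-type pseudobulks — per type, test cells are partitioned into two
  equal groups and summed gene-wise (Replicates 1 and 2);
* mixed pseudobulks — per sample and type, a proportion is drawn from a
  normal distribution whose mean and SD both equal the type's proportion in
  the reference, negatives are clamped to 0, scaled by the target mean cell
  count (600) and rounded to a cell count; the drawn cells' counts are summed.

Ground truth for scoring is the *realized* fraction (cells actually drawn),
since clamping and rounding make the intended draw vector unnormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SplitResult",
    "MixedBulkSet",
    "split_train_test",
    "simulate_single_type_bulks",
    "simulate_mixed_bulks",
    "cells_from_draws",
]


@dataclass
class SplitResult:
    train_cells: pd.Index
    test_cells: pd.Index
    per_type: pd.DataFrame  # columns train/test, one row per type


@dataclass
class MixedBulkSet:
    counts: pd.DataFrame             # genes x samples
    intended_draws: pd.DataFrame     # samples x types, raw normal draws
    realized_fractions: pd.DataFrame  # samples x types, from cells drawn
    cells_used: pd.DataFrame         # samples x types, integer counts


def split_train_test(labels: pd.Series, train_fraction: float = 0.75, seed: int = 0):
    """Stratified per-type split: round(train_fraction * n) training cells,
    the remainder held out, with at least one test cell per type."""
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train, test, rows = [], [], []
    for t, cells in labels.groupby(labels):
        ids = cells.index.to_numpy()
        if len(ids) < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(n_train, len(ids) - 1)  # keep >=1 test cell
        perm = rng.permutation(len(ids))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
        rows.append({"cell_type": t, "train": n_train, "test": len(ids) - n_train})
    per_type = pd.DataFrame(rows).set_index("cell_type")
    return SplitResult(pd.Index(train), pd.Index(test), per_type)


def simulate_single_type_bulks(
    counts: pd.DataFrame, labels: pd.Series, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Two pseudobulk replicates per type: test cells randomly partitioned
    into two equal groups (odd counts differ by one) and summed gene-wise.

    Returns the genes x samples matrix and the sample -> type labelling.
    Types with fewer than 2 cells are skipped with a warning.
    """
    labels = pd.Series(labels).loc[counts.columns]
    rng = np.random.default_rng(seed)
    cols, names, truth = [], [], []
    for t, cells in labels.groupby(labels):
        ids = cells.index.to_numpy()
        if len(ids) < 2:
            logger.warning("type %r has <2 cells; skipped", t)
            continue
        perm = rng.permutation(len(ids))
        half = (len(ids) + 1) // 2
        for rep, sel in enumerate((perm[:half], perm[half:]), start=1):
            cols.append(counts[ids[sel]].sum(axis=1).to_numpy())
            names.append(f"{t}_rep{rep}")
            truth.append(t)
    bulk = pd.DataFrame(np.column_stack(cols), index=counts.index, columns=names)
    return bulk, pd.Series(truth, index=names, name="true_type")


def cells_from_draws(draws: np.ndarray, mean_cells: int) -> np.ndarray:
    """The stated clamp/round rule: negatives to 0, scale by the target mean
    cell count, round to integers."""
    return np.round(np.clip(np.asarray(draws, dtype=float), 0.0, None) * mean_cells).astype(int)


def simulate_mixed_bulks(
    counts: pd.DataFrame,
    labels: pd.Series,
    reference_proportions: pd.Series | None = None,
    n_samples: int = 500,
    mean_cells: int = 600,
    with_replacement: bool = False,
    seed: int = 0,
) -> MixedBulkSet:
    """Mixed pseudobulks with ground-truth composition.

    Per sample and type k, draw ~ Normal(p_k, p_k) with p_k the type's
    proportion in ``reference_proportions`` (default: proportions within
    ``labels``); negatives clamp to 0; cell count = round(draw * mean_cells).
    Without replacement the count is capped at the available test cells
    (logged when the cap binds).  A sample whose draws all clamp to zero is
    resampled (logged).
    """
    labels = pd.Series(labels).loc[counts.columns]
    types = sorted(labels.unique())
    pools = {t: labels.index[labels == t].to_numpy() for t in types}
    if reference_proportions is None:
        reference_proportions = labels.value_counts(normalize=True)
    p = reference_proportions.reindex(types).to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any():
        raise ValueError("reference_proportions must cover all types, >= 0")

    rng = np.random.default_rng(seed)
    X = counts.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(counts.columns)}
    pool_pos = {t: np.array([col_pos[c] for c in pools[t]]) for t in types}

    draws = np.empty((n_samples, len(types)))
    used = np.zeros((n_samples, len(types)), dtype=int)
    bulk = np.zeros((X.shape[0], n_samples))
    n_capped = 0
    for j in range(n_samples):
        while True:
            d = rng.normal(p, p)
            n_cells = cells_from_draws(d, mean_cells)
            if n_cells.sum() > 0:
                break
            logger.info("sample %d: all draws clamped to zero; resampled", j)
        draws[j] = d
        for k, t in enumerate(types):
            want = n_cells[k]
            if want == 0:
                continue
            avail = len(pool_pos[t])
            if with_replacement:
                sel = rng.integers(0, avail, size=want)
            else:
                if want > avail:
                    n_capped += 1
                    want = avail
                sel = rng.permutation(avail)[:want]
            used[j, k] = want
            bulk[:, j] += X[:, pool_pos[t][sel]].sum(axis=1)
    if n_capped:
        logger.info(
            "cell-count cap bound in %d of %d sample-type draws",
            n_capped, n_samples * len(types),
        )

    sample_ids = [f"mix{j:04d}" for j in range(n_samples)]
    totals = used.sum(axis=1, keepdims=True)
    realized = used / np.where(totals > 0, totals, 1)
    return MixedBulkSet(
        counts=pd.DataFrame(bulk, index=counts.index, columns=sample_ids),
        intended_draws=pd.DataFrame(draws, index=sample_ids, columns=types),
        realized_fractions=pd.DataFrame(realized, index=sample_ids, columns=types),
        cells_used=pd.DataFrame(used, index=sample_ids, columns=types),
    )
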