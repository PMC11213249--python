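"""Marker-gene signature matrix construction from a labelled reference.

The signature matrix is the deconvolution basis: characteristic per-type mean
expression of marker genes, on the linear scale.  Construction follows the
published signature-matrix conventions:

1. genes with ln(total read count) outside [4, 10] are removed (very lowly or
   very highly expressed genes carry little cell-type signal or dominate fits);
2. cells are depth-normalized to counts-per-10,000 — linear scale, no
   quantile normalization;
3. per type, genes are ranked one-vs-rest by a two-sided Wilcoxon rank-sum
   test, kept at Benjamini-Hochberg q below a threshold and fold change > 1,
   then ordered by fold change (ties broken by gene id);
4. candidate signatures take the top-g markers of every type for g across a
   search range; the g minimizing the 2-norm condition number of the
   resulting matrix is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFilterBounds",
    "SignatureMatrix",
    "SignatureBuilder",
    "filter_genes",
    "build_signature",
    "IllConditionedSignatureWarning",
]


class IllConditionedSignatureWarning(UserWarning):
    """The selected signature is close to singular (near-duplicate types)."""


@dataclass
class GeneFilterBounds:
    """Inclusive bounds on ln(total read count) of a gene across all cells."""

    low: float = 4.0
    high: float = 10.0

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("GeneFilterBounds requires low < high")


@dataclass
class SignatureMatrix:
    """Marker-genes x cell-types basis with its condition number."""

    values: pd.DataFrame            # markers x types, linear-scale means
    condition_number: float
    markers_per_type_used: int
    markers: dict[str, list[str]] | None = None  # per-type ranked marker ids

    @property
    def marker_ids(self):
        return self.values.index

    @property
    def type_ids(self):
        return self.values.columns


def filter_genes(
    counts: pd.DataFrame, bounds: GeneFilterBounds | None = None
) -> pd.Index:
    """Return the genes whose ln(total count) lies inside ``bounds``.

    Genes with zero total are always removed.  Raises if nothing survives.
    """
    bounds = bounds or GeneFilterBounds()
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ln_tot = np.log(totals)
    keep = (totals > 0) & (ln_tot >= bounds.low) & (ln_tot <= bounds.high)
    if not keep.any():
        raise ValueError(
            "gene filter removed every gene; adjust GeneFilterBounds "
            f"(low={bounds.low}, high={bounds.high})"
        )
    return counts.index[keep]


def _cp10k(counts: np.ndarray) -> np.ndarray:
    """Counts-per-10,000 per cell; zero-total cells are left at zero."""
    totals = counts.sum(axis=0, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return counts * (1e4 / safe)


class SignatureBuilder(BaseEstimator):
    """Build a deconvolution signature from labelled single cells.

    scikit-learn conventions: ``fit(X, y)`` takes ``X`` as a cells x genes
    DataFrame (gene ids as columns) and ``y`` as the per-cell type labels.

    Parameters
    ----------
    low, high : bounds on ln(gene total count) for the pre-filter.
    q_max : Benjamini-Hochberg q threshold for one-vs-rest markers.
    markers_min, markers_max : search range for markers kept per type; when a
        type's significant pool is smaller than g, the whole pool is used.

    Attributes
    ----------
    signature_ : DataFrame, marker genes x types (linear-scale means).
    condition_number_ : float, 2-norm condition number of ``signature_``.
    markers_per_type_used_ : int, the selected g.
    markers_ : dict, per-type ranked marker gene ids (full significant pool).
    """

    def __init__(
        self,
        low: float = 4.0,
        high: float = 10.0,
        q_max: float = 0.3,
        markers_min: int = 50,
        markers_max: int = 150,
        condition_warn: float = 1e6,
    ):
        self.low = low
        self.high = high
        self.q_max = q_max
        self.markers_min = markers_min
        self.markers_max = markers_max
        self.condition_warn = condition_warn

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        counts = X.T  # genes x cells, the on-disk orientation
        labels = pd.Series(np.asarray(y), index=counts.columns)

        types = sorted(labels.unique())
        if len(types) < 2:
            raise ValueError("need at least 2 cell types")
        sizes = labels.value_counts()
        small = sizes[sizes < 3]
        if len(small):
            raise ValueError(
                f"cell types with fewer than 3 cells: {list(small.index)}"
            )

        kept = filter_genes(counts, GeneFilterBounds(self.low, self.high))
        counts = counts.loc[kept]
        norm = _cp10k(counts.to_numpy(dtype=float))
        genes = counts.index.to_numpy()

        type_masks = {t: (labels == t).to_numpy() for t in types}
        means = {t: norm[:, m].mean(axis=1) for t, m in type_masks.items()}

        markers: dict[str, list[str]] = {}
        for t in types:
            mask = type_masks[t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                stat_p = mannwhitneyu(
                    norm[:, mask], norm[:, ~mask], axis=1,
                    alternative="two-sided",
                ).pvalue
            stat_p = np.nan_to_num(stat_p, nan=1.0)
            q = multipletests(stat_p, method="fdr_bh")[1]
            rest_mean = norm[:, ~mask].mean(axis=1)
            fold = (means[t] + 1e-9) / (rest_mean + 1e-9)
            sig = (q < self.q_max) & (fold > 1.0)
            if not sig.any():
                raise ValueError(f"no significant markers for type {t!r}")
            order = np.lexsort((genes[sig], -fold[sig]))
            markers[t] = list(genes[sig][order])

        mean_table = pd.DataFrame(means, index=counts.index)[types]
        best = None
        for g in range(self.markers_min, self.markers_max + 1):
            union: list[str] = []
            seen = set()
            for t in types:
                for gene in markers[t][:g]:
                    if gene not in seen:
                        seen.add(gene)
                        union.append(gene)
            cand = mean_table.loc[union]
            cond = np.linalg.cond(cand.to_numpy())
            if best is None or cond < best[0] - 1e-12:
                best = (cond, g, cand)

        cond, g, cand = best
        if not np.isfinite(cond) or cond > self.condition_warn:
            warnings.warn(
                f"signature condition number {cond:.3g}: near-duplicate cell "
                "types make the deconvolution ill-posed",
                IllConditionedSignatureWarning,
            )
        logger.info(
            "signature: %d genes, %d types, g=%d, condition number %.3g",
            cand.shape[0], cand.shape[1], g, cond,
        )
        self.signature_ = cand
        self.condition_number_ = float(cond)
        self.markers_per_type_used_ = g
        self.markers_ = markers
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def result_(self) -> SignatureMatrix:
        return SignatureMatrix(
            values=self.signature_,
            condition_number=self.condition_number_,
            markers_per_type_used=self.markers_per_type_used_,
            markers=self.markers_,
        )


def build_signature(
    counts: pd.DataFrame,
    labels,
    markers_range: tuple[int, int] = (50, 150),
    q_threshold: float = 0.3,
    bounds: GeneFilterBounds | None = None,
) -> SignatureMatrix:
    """Functional wrapper over :class:`SignatureBuilder` taking the on-disk
    genes x cells orientation."""
    bounds = bounds or GeneFilterBounds()
    builder = SignatureBuilder(
        low=bounds.low,
        high=bounds.high,
        q_max=q_threshold,
        markers_min=markers_range[0],
        markers_max=markers_range[1],
    )
    builder.fit(counts.T, np.asarray(labels))
    return builder.result_
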