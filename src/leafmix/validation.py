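"""Scoring of deconvolution output against ground truth.

Three views of accuracy, matching how deconvolution benchmarks are reported:

* per-type Pearson correlation across samples between true and predicted
  fractions (threshold of interest r > 0.8);
* per-type slope of the ordinary-least-squares line of best fit of predicted
  on true (1 is unbiased; systematic over/under-prediction shows as slope
  away from 1);
* single-type classification: the argmax predicted type of each single-type
  pseudobulk, accumulated into a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "BenchmarkReport",
    "per_type_correlation",
    "fit_slope",
    "classify_single_type",
    "benchmark_report",
]


@dataclass
class BenchmarkReport:
    per_type: pd.DataFrame            # pearson_r, pearson_p, slope, intercept, r_gt_0.8
    confusion: pd.DataFrame | None    # true x predicted counts


def _align(true_fractions: pd.DataFrame, predicted: pd.DataFrame):
    samples = true_fractions.index.intersection(predicted.index)
    types = true_fractions.columns.intersection(predicted.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 matched samples")
    if len(types) == 0:
        raise ValueError("no shared cell types between tables")
    return true_fractions.loc[samples, types], predicted.loc[samples, types]


def per_type_correlation(
    true_fractions: pd.DataFrame, predicted: pd.DataFrame
) -> pd.DataFrame:
    """Across samples, per type: Pearson r and two-sided p between true and
    predicted fractions.  Constant columns give missing (NaN) values."""
    t, p = _align(true_fractions, predicted)
    rows = {}
    for typ in t.columns:
        x, y = t[typ].to_numpy(float), p[typ].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            rows[typ] = (np.nan, np.nan)
        else:
            r, pv = scipy.stats.pearsonr(x[ok], y[ok])
            rows[typ] = (r, pv)
    return pd.DataFrame(rows, index=["pearson_r", "pearson_p"]).T


def fit_slope(true_fractions: pd.DataFrame, predicted: pd.DataFrame) -> pd.DataFrame:
    """Per type, OLS slope (and intercept) of predicted on true fractions.
    Zero-variance truth gives missing values."""
    t, p = _align(true_fractions, predicted)
    rows = {}
    for typ in t.columns:
        x, y = t[typ].to_numpy(float), p[typ].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or x[ok].std() == 0:
            rows[typ] = (np.nan, np.nan)
        else:
            res = scipy.stats.linregress(x[ok], y[ok])
            rows[typ] = (res.slope, res.intercept)
    return pd.DataFrame(rows, index=["slope", "intercept"]).T


def classify_single_type(
    predicted: pd.DataFrame, true_labels: pd.Series
) -> pd.DataFrame:
    """Confusion matrix of argmax-fraction classification of single-type
    pseudobulks; exact ties resolve to the lexicographically first type id."""
    true_labels = pd.Series(true_labels).loc[predicted.index]
    cols = sorted(predicted.columns)
    pred_sorted = predicted[cols]
    calls = []
    for _, row in pred_sorted.iterrows():
        m = row.max()
        calls.append(next(c for c in cols if row[c] == m))
    all_types = sorted(set(cols) | set(true_labels.unique()))
    confusion = pd.DataFrame(0, index=all_types, columns=all_types)
    for t, c in zip(true_labels, calls):
        confusion.loc[t, c] += 1
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    return confusion


def benchmark_report(
    true_fractions: pd.DataFrame,
    predicted: pd.DataFrame,
    single_type_predicted: pd.DataFrame | None = None,
    single_type_labels: pd.Series | None = None,
    r_threshold: float = 0.8,
) -> BenchmarkReport:
    """Combined accuracy report over the mixed and single-type benchmarks.
    Invariant to sample order (all statistics are computed per matched pair)."""
    corr = per_type_correlation(true_fractions, predicted)
    slope = fit_slope(true_fractions, predicted)
    per_type = corr.join(slope)
    per_type[f"r_gt_{r_threshold:g}"] = per_type["pearson_r"] > r_threshold
    confusion = None
    if single_type_predicted is not None and single_type_labels is not None:
        confusion = classify_single_type(single_type_predicted, single_type_labels)
    return BenchmarkReport(per_type=per_type, confusion=confusion)
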