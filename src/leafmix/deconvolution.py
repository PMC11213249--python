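"""Estimation of cell-type activity fractions from bulk expression.

The model: a bulk profile is approximately a non-negative mixture of
cell-type signature columns, ``b ~ S f`` with ``f >= 0``.  Fractions are the
normalized mixture coefficients — the share of transcripts attributable to
each type's expression program, not a cell count.  Two engines satisfy the
contract:

* ``nnls`` — non-negative least squares (deterministic, default);
* ``svr``  — linear-kernel nu-support-vector regression over
  nu in {0.25, 0.5, 0.75}, keeping the lowest-RMSE fit, with negative
  coefficients clamped to zero.

Fit significance is a permutation test: the reconstruction correlation of the
observed fit is compared with fits on gene-label-permuted signatures; the
p-value uses +1 smoothing so p lies in (0, 1].

Inputs are used on the linear scale; quantile normalization is deliberately
not applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator
from sklearn.svm import NuSVR

from .signature import SignatureBuilder, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FractionTable",
    "ImputedProfiles",
    "Deconvolver",
    "deconvolve",
    "impute_group_expression",
    "assign_gene_to_celltype",
]

_MIN_SHARED_GENES = 10


@dataclass
class FractionTable:
    """Per-sample cell-type fractions with fit diagnostics.

    ``fractions`` rows are non-negative and sum to 1; all-zero bulk samples
    are flagged in ``undefined`` and carry NaN fractions.
    """

    fractions: pd.DataFrame          # samples x types
    fit_rmse: pd.Series
    fit_correlation: pd.Series
    permutation_p: pd.Series | None
    undefined: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.fractions.copy()
        out["fit_rmse"] = self.fit_rmse
        out["fit_correlation"] = self.fit_correlation
        if self.permutation_p is not None:
            out["permutation_p"] = self.permutation_p
        return out


@dataclass
class ImputedProfiles:
    """Group-mode imputed cell-type expression (types x genes)."""

    values: pd.DataFrame
    types_used: list[str]
    degenerate: bool = False


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _fit_nnls(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    coef, _ = scipy.optimize.nnls(S, b)
    return coef


class _SvrEngine:
    def __init__(self, nu_grid=(0.25, 0.5, 0.75), c: float = 1.0):
        self.nu_grid = nu_grid
        self.c = c

    def __call__(self, S: np.ndarray, b: np.ndarray) -> np.ndarray:
        # standardize per sample: response and signature columns on z-scales
        mu, sd = S.mean(axis=0), S.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (S - mu) / sd
        bs_sd = b.std() or 1.0
        ys = (b - b.mean()) / bs_sd
        best = None
        for nu in self.nu_grid:
            model = NuSVR(nu=nu, C=self.c, kernel="linear")
            model.fit(Xs, ys)
            w = np.clip(model.coef_.ravel() / sd, 0.0, None)
            recon = S @ w
            rmse = float(np.sqrt(np.mean((recon * _scale(recon, b) - b) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, w)
        return best[1]


def _scale(recon: np.ndarray, b: np.ndarray) -> float:
    denom = float(recon @ recon)
    return float(recon @ b) / denom if denom > 0 else 1.0


class Deconvolver(BaseEstimator):
    """Signature-based bulk deconvolution as a scikit-learn estimator.

    Two ways to obtain the signature:

    * pass a prebuilt one (``signature=`` a DataFrame or
      :class:`SignatureMatrix`) and call ``fit(None)`` or ``predict`` directly
      after ``fit``;
    * call ``fit(X, y)`` with a cells x genes matrix and per-cell labels, and
      the signature is built internally with :class:`SignatureBuilder`
      parameters taken from ``builder``.

    ``predict(X)`` takes bulk samples x genes and returns the fraction matrix
    (samples x types, rows on the simplex).  ``predict_table`` adds fit
    diagnostics and the permutation p-value.
    """

    def __init__(
        self,
        signature=None,
        method: str = "nnls",
        n_perm: int = 100,
        random_state: int | None = None,
        builder: SignatureBuilder | None = None,
        nu_grid: tuple = (0.25, 0.5, 0.75),
        svr_c: float = 1.0,
    ):
        self.signature = signature
        self.method = method
        self.n_perm = n_perm
        self.random_state = random_state
        self.builder = builder
        self.nu_grid = nu_grid
        self.svr_c = svr_c

    # -- fitting ----------------------------------------------------------
    def fit(self, X=None, y=None):
        if self.signature is not None:
            sig = self.signature
            if isinstance(sig, SignatureMatrix):
                sig = sig.values
            if not isinstance(sig, pd.DataFrame):
                raise TypeError("signature must be a DataFrame or SignatureMatrix")
            self.signature_ = sig
        else:
            if X is None or y is None:
                raise ValueError("fit needs (X, y) when no signature is supplied")
            builder = self.builder or SignatureBuilder()
            builder.fit(X, y)
            self.signature_ = builder.signature_
            self.builder_ = builder
        if (self.signature_.to_numpy() < 0).any():
            raise ValueError("signature contains negative values")
        self.types_ = list(self.signature_.columns)
        return self

    def _engine(self):
        if self.method == "nnls":
            return _fit_nnls
        if self.method == "svr":
            return _SvrEngine(self.nu_grid, self.svr_c)
        raise ValueError(f"unknown method {self.method!r}")

    # -- prediction -------------------------------------------------------
    def predict(self, X) -> pd.DataFrame:
        return self.predict_table(self._as_bulk(X), n_perm=0).fractions

    def _as_bulk(self, X) -> pd.DataFrame:
        """Accept samples x genes (estimator orientation) and return
        genes x samples."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X), columns=self.signature_.index[: np.shape(X)[1]]
            )
        return X.T

    def predict_table(self, bulk: pd.DataFrame, n_perm: int | None = None):
        """Deconvolve a genes x samples bulk matrix.

        Restricts to genes shared with the signature (>= 10 required), solves
        per sample, clamps negatives, normalizes rows to sum 1, and (when
        ``n_perm`` > 0) attaches permutation p-values.
        """
        if n_perm is None:
            n_perm = self.n_perm
        sig = self.signature_
        shared = sig.index.intersection(bulk.index)
        logger.info(
            "deconvolve: %d/%d signature genes found in bulk",
            len(shared), sig.shape[0],
        )
        if len(shared) == 0:
            raise ValueError("no overlap between signature and bulk gene ids")
        if len(shared) < _MIN_SHARED_GENES:
            raise ValueError(
                f"only {len(shared)} signature genes shared with the bulk "
                f"matrix; need >= {_MIN_SHARED_GENES}"
            )
        S = sig.loc[shared].to_numpy(dtype=float)
        B = bulk.loc[shared].to_numpy(dtype=float)
        engine = self._engine()
        rng = np.random.default_rng(self.random_state)
        perms = (
            [rng.permutation(S.shape[0]) for _ in range(n_perm)] if n_perm else []
        )

        n_samples = B.shape[1]
        fracs = np.full((n_samples, S.shape[1]), np.nan)
        rmse = np.full(n_samples, np.nan)
        corr = np.full(n_samples, np.nan)
        pval = np.full(n_samples, np.nan)
        undefined = np.zeros(n_samples, dtype=bool)
        for j in range(n_samples):
            b = B[:, j]
            if not b.any():
                undefined[j] = True
                logger.warning(
                    "bulk sample %s is all zero; fractions undefined",
                    bulk.columns[j],
                )
                continue
            coef = np.clip(engine(S, b), 0.0, None)
            recon = S @ coef
            rmse[j] = np.sqrt(np.mean((recon - b) ** 2))
            r_obs = _pearson(recon, b)
            corr[j] = r_obs
            total = coef.sum()
            fracs[j] = coef / total if total > 0 else np.nan
            if total == 0:
                undefined[j] = True
            if perms:
                exceed = 0
                for perm in perms:
                    coef_p = np.clip(engine(S[perm], b), 0.0, None)
                    r_p = _pearson(S[perm] @ coef_p, b)
                    if not np.isnan(r_p) and r_p >= r_obs:
                        exceed += 1
                pval[j] = (1 + exceed) / (n_perm + 1)

        idx = bulk.columns
        return FractionTable(
            fractions=pd.DataFrame(fracs, index=idx, columns=self.types_),
            fit_rmse=pd.Series(rmse, index=idx, name="fit_rmse"),
            fit_correlation=pd.Series(corr, index=idx, name="fit_correlation"),
            permutation_p=(
                pd.Series(pval, index=idx, name="permutation_p") if perms else None
            ),
            undefined=pd.Series(undefined, index=idx, name="undefined"),
        )


def deconvolve(
    bulk: pd.DataFrame,
    signature,
    method: str = "nnls",
    n_perm: int = 100,
    seed: int | None = None,
) -> FractionTable:
    """Deconvolve a genes x samples bulk matrix against a signature."""
    model = Deconvolver(
        signature=signature, method=method, n_perm=n_perm, random_state=seed
    ).fit()
    return model.predict_table(bulk, n_perm=n_perm)


def impute_group_expression(
    bulk: pd.DataFrame,
    fractions,
    gene_set=None,
    n_abundant: int = 9,
) -> ImputedProfiles:
    """Group-mode imputation of cell-type expression.

    Types are ranked by mean fraction; the ``n_abundant`` most abundant are
    kept and the remainder collapsed into ``"other"`` (fractions summed).
    Per gene, the across-samples system ``bulk_gene ~ F h`` is solved by
    non-negative least squares, giving one expression value per retained type.
    """
    F = fractions.fractions if isinstance(fractions, FractionTable) else fractions
    F = F.loc[:, ~F.columns.isin(["fit_rmse", "fit_correlation", "permutation_p"])]
    shared_samples = F.index.intersection(bulk.columns)
    if len(shared_samples) == 0:
        raise ValueError("no samples shared between bulk and fractions")
    F = F.loc[shared_samples]
    bulk = bulk[shared_samples]

    order = F.mean(axis=0).sort_values(ascending=False).index
    top = list(order[:n_abundant])
    rest = list(order[n_abundant:])
    reduced = F[top].copy()
    if rest:
        reduced["other"] = F[rest].sum(axis=1)
    types_used = list(reduced.columns)
    if len(shared_samples) < len(types_used):
        raise ValueError(
            f"{len(shared_samples)} samples cannot constrain {len(types_used)} types"
        )

    genes = bulk.index if gene_set is None else bulk.index.intersection(gene_set)
    if len(genes) == 0:
        raise ValueError("requested gene set absent from the bulk matrix")

    A = reduced.to_numpy(dtype=float)
    degenerate = np.linalg.matrix_rank(A) < A.shape[1]
    if degenerate:
        logger.warning(
            "fraction matrix is rank-deficient (%d types, rank %d); imputed "
            "values are not unique",
            A.shape[1], np.linalg.matrix_rank(A),
        )
    vals = np.empty((len(types_used), len(genes)))
    B = bulk.loc[genes].to_numpy(dtype=float)
    for i in range(len(genes)):
        vals[:, i], _ = scipy.optimize.nnls(A, B[i])
    return ImputedProfiles(
        values=pd.DataFrame(vals, index=types_used, columns=genes),
        types_used=types_used,
        degenerate=bool(degenerate),
    )


def assign_gene_to_celltype(
    imputed: ImputedProfiles | pd.DataFrame, alpha: float = 0.5
) -> pd.DataFrame:
    """Binary gene -> cell-type assignment: a gene belongs to every type whose
    imputed value is >= alpha times the gene's maximum; all-zero genes are
    left unassigned.  Returns genes x types booleans with the rule parameter
    recorded in ``attrs``."""
    values = imputed.values if isinstance(imputed, ImputedProfiles) else imputed
    V = values.to_numpy(dtype=float).T  # genes x types
    row_max = V.max(axis=1, keepdims=True)
    assigned = (V >= alpha * row_max) & (row_max > 0)
    out = pd.DataFrame(assigned, index=values.columns, columns=values.index)
    out.attrs["alpha"] = alpha
    return out
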