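"""Dimensionality reduction for single-cell protein matrices.

Two flavors are used in this workflow:

* :class:`WeightedPCA` — PCA on a complete (imputed) matrix in which each
  protein is weighted by the summed squared Pearson correlation of that
  protein with every protein (self term included), so proteins that
  covary with many others dominate the projection;
* :class:`PairwiseCorrelationPCA` — eigenvectors of the cell x cell
  Pearson correlation matrix computed on pairwise-observed values only,
  which needs no imputation and is invariant to per-cell affine scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import pairwise_complete_corr

__all__ = ["WeightedPCA", "PairwiseCorrelationPCA", "PCAResult",
           "weighted_pca", "corr_pca", "project_bulk"]


@dataclass
class PCAResult:
    """Scores/loadings container used by the module-level wrappers."""

    scores: pd.DataFrame                    # cells x components
    loadings: Optional[pd.DataFrame]        # proteins x components (or None)
    explained_variance_fraction: np.ndarray
    weights: Optional[pd.Series] = None     # per-protein (weighted variant)
    estimator: Optional[BaseEstimator] = None


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Deterministic orientation: the largest-|value| loading is positive."""
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return loadings, scores


class WeightedPCA(TransformerMixin, BaseEstimator):
    """Correlation-weighted principal component analysis.

    Each protein's weight is ``w_i = sum_j r_ij**2`` over the protein x
    protein Pearson correlation matrix (self term included, so an
    uncorrelated protein gets weight 1); centered protein values are
    multiplied by ``w_i`` before the singular value decomposition.
    Setting ``unit_weights=True`` reduces to standard PCA.

    The input is cells x proteins and must be complete — impute first.
    """

    def __init__(self, n_components: int = 2, unit_weights: bool = False):
        self.n_components = n_components
        self.unit_weights = unit_weights

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("X contains missing values; impute before "
                             "weighted PCA (e.g. CellSimilarityImputer)")
        n, p = X.shape
        if n < 3 or p < 3:
            raise ValueError("need at least 3 cells and 3 proteins")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.unit_weights:
            w = np.ones(p)
        else:
            sd = Xc.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                Z = np.where(sd > 0, Xc / sd, 0.0)
                r = (Z.T @ Z) / n
            r[~np.isfinite(r)] = 0.0
            np.fill_diagonal(r, 1.0)  # zero-variance proteins keep the self term
            w = (r ** 2).sum(axis=0)
        self.weights_ = w
        U, S, Vt = np.linalg.svd(Xc * w, full_matrices=False)
        k = min(self.n_components, S.size)
        ev = S ** 2
        self.explained_variance_ratio_ = (ev / ev.sum())[:k]
        loadings = Vt.T[:, :k].copy()
        scores = (U[:, :k] * S[:k]).copy()
        self.components_, self._train_scores_ = _fix_signs(loadings, scores)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        Xc = np.where(np.isfinite(X), X - self.mean_, 0.0)  # missing -> 0 after centering
        return (Xc * self.weights_) @ self.components_

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self._train_scores_


class PairwiseCorrelationPCA(BaseEstimator):
    """Embedding from the pairwise-complete cell x cell correlation matrix.

    No imputation is performed; cell pairs sharing fewer than
    ``min_shared`` observed proteins get correlation 0 (their count is
    recorded in ``n_low_overlap_``).  Scores are the top eigenvectors of
    the correlation matrix.
    """

    def __init__(self, n_components: int = 2, min_shared: int = 3):
        self.n_components = n_components
        self.min_shared = min_shared

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        C, n = pairwise_complete_corr(X.T, min_shared=self.min_shared, fill=0.0)
        off = n.copy()
        np.fill_diagonal(off, 0)
        isolated = np.where((off < self.min_shared).all(axis=1))[0]
        if isolated.size and X.shape[0] > 1:
            raise ValueError(f"cell index {isolated[0]} shares no observations "
                             "with any other cell")
        self.n_low_overlap_ = int(((off < self.min_shared).sum() - 0) // 2)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        k = min(self.n_components, evals.size)
        top = order[:k]
        scores = evecs[:, top].copy()
        scores, _ = _fix_signs(scores, scores.copy())
        self.scores_ = scores
        self.eigenvalues_ = evals[top]
        tot = np.clip(evals, 0, None).sum()
        self.explained_variance_ratio_ = np.clip(evals[top], 0, None) / tot if tot > 0 \
            else np.zeros(k)
        self.correlation_ = C
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_


def weighted_pca(m: pd.DataFrame, n_components: int = 2,
                 unit_weights: bool = False) -> PCAResult:
    """Weighted PCA of a protein x cell matrix (cells become samples)."""
    est = WeightedPCA(n_components=n_components, unit_weights=unit_weights)
    scores = est.fit_transform(m.T.to_numpy(float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.columns, columns=cols),
        loadings=pd.DataFrame(est.components_, index=m.index, columns=cols),
        explained_variance_fraction=est.explained_variance_ratio_,
        weights=pd.Series(est.weights_, index=m.index, name="weight"),
        estimator=est,
    )


def corr_pca(m: pd.DataFrame, n_components: int = 2,
             min_shared: int = 3) -> PCAResult:
    """Correlation-matrix PCA of a protein x cell matrix."""
    est = PairwiseCorrelationPCA(n_components=n_components, min_shared=min_shared)
    scores = est.fit_transform(m.T.to_numpy(float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.columns, columns=cols),
        loadings=None,
        explained_variance_fraction=est.explained_variance_ratio_,
        estimator=est,
    )


def project_bulk(pca: PCAResult, bulk: pd.DataFrame,
                 min_shared: int = 10) -> pd.DataFrame:
    """Project bulk samples (protein x sample matrix) onto fitted loadings.

    Bulk proteins are intersected with the loading space; proteins absent
    from a bulk column contribute zero after centering.
    """
    if pca.loadings is None or pca.estimator is None:
        raise ValueError("projection requires a loadings-based (weighted) PCA")
    shared = pca.loadings.index.intersection(bulk.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} proteins shared with the PCA space "
                         f"(need >= {min_shared})")
    est: WeightedPCA = pca.estimator
    full = pd.DataFrame(np.nan, index=pca.loadings.index, columns=bulk.columns)
    full.loc[shared] = bulk.loc[shared].to_numpy(float)
    scores = est.transform(full.T.to_numpy(float))
    return pd.DataFrame(scores, index=bulk.columns, columns=pca.scores.columns)
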