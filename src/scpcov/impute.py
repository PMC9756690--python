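"""k-nearest-neighbor imputation of missing protein levels.

Neighbors are cells, similarity is Pearson correlation over pairwise-
observed proteins (the SCoPE2 convention); a missing (protein, cell)
entry is filled with the unweighted mean of that protein's observed
values among the k most similar cells that observe it.  Observed entries
are never altered.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import pairwise_complete_corr

log = logging.getLogger(__name__)

__all__ = ["CellSimilarityImputer", "knn_impute"]


class CellSimilarityImputer(TransformerMixin, BaseEstimator):
    """Impute a cells x features matrix from its most similar cells.

    Parameters
    ----------
    k : int
        Number of neighbor cells averaged per missing entry.
    metric : {"correlation", "euclidean"}
        Cell-cell similarity. Correlation is computed on pairwise-observed
        features; euclidean uses the negative mean squared difference on
        the shared support.
    min_shared : int
        Cell pairs sharing fewer observed features get similarity -inf
        (never chosen as neighbors).

    Attributes
    ----------
    X_ : ndarray
        The training matrix (donor cells).
    similarity_ : ndarray
        Cell x cell similarity among training cells.
    n_fallback_ : int
        Entries that had no observing neighbor and were filled with the
        feature mean (counted and logged).
    """

    def __init__(self, k: int = 3, metric: str = "correlation", min_shared: int = 3):
        self.k = k
        self.metric = metric
        self.min_shared = min_shared

    def _similarity(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "correlation":
            s, n = pairwise_complete_corr(X.T, min_shared=self.min_shared,
                                          fill=-np.inf)
            s[n < self.min_shared] = -np.inf
            return s
        if self.metric == "euclidean":
            n_cells = X.shape[0]
            s = np.full((n_cells, n_cells), -np.inf)
            M = np.isfinite(X)
            for i in range(n_cells):
                shared = M[i] & M
                cnt = shared.sum(axis=1)
                diff = np.where(shared, X[i] - X, 0.0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    msd = (diff ** 2).sum(axis=1) / cnt
                ok = cnt >= self.min_shared
                s[i, ok] = -msd[ok]
            return s
        raise ValueError(f"unknown metric {self.metric!r}")

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.X_ = X
        self.similarity_ = self._similarity(X)
        np.fill_diagonal(self.similarity_, -np.inf)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float)
        same = X.shape == self.X_.shape and np.array_equal(
            np.isfinite(X), np.isfinite(self.X_)) and np.allclose(
            np.nan_to_num(X), np.nan_to_num(self.X_))
        donors = self.X_
        Mdon = np.isfinite(donors)
        Vdon = np.where(Mdon, donors, 0.0)
        col_mean = np.where(Mdon.any(axis=0),
                            Vdon.sum(axis=0) / np.maximum(Mdon.sum(axis=0), 1),
                            np.nan)
        out = X.copy()
        self.n_fallback_ = 0
        for i in range(X.shape[0]):
            miss = ~np.isfinite(X[i])
            if not miss.any():
                continue
            if same:
                sim = self.similarity_[i]
            else:
                sim = self._cross_similarity(X[i])
            order = np.argsort(-sim, kind="stable")
            usable = np.isfinite(sim[order])
            order = order[usable]
            O = Mdon[order][:, miss]
            V = Vdon[order][:, miss]
            cnt = np.cumsum(O, axis=0)
            val = np.cumsum(V, axis=0)
            total = cnt[-1] if cnt.size else np.zeros(miss.sum(), int)
            filled = np.empty(miss.sum())
            for j in range(miss.sum()):
                if total[j] == 0:
                    filled[j] = col_mean[np.where(miss)[0][j]]
                    self.n_fallback_ += 1
                elif total[j] <= self.k:
                    filled[j] = val[-1, j] / total[j]
                else:
                    row = int(np.searchsorted(cnt[:, j], self.k))
                    filled[j] = val[row, j] / cnt[row, j]
            out[i, miss] = filled
        if self.n_fallback_:
            log.warning("%d entries had no observing neighbor; "
                        "filled with feature means", self.n_fallback_)
        return out

    def _cross_similarity(self, x: np.ndarray) -> np.ndarray:
        """Similarity of one (possibly new) cell to every training cell."""
        donors = self.X_
        mx = np.isfinite(x)
        out = np.full(donors.shape[0], -np.inf)
        for j in range(donors.shape[0]):
            m = mx & np.isfinite(donors[j])
            if m.sum() < self.min_shared:
                continue
            if self.metric == "euclidean":
                out[j] = -np.mean((x[m] - donors[j, m]) ** 2)
            else:
                a, b = x[m], donors[j, m]
                sa, sb = a.std(), b.std()
                if sa > 0 and sb > 0:
                    out[j] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
        return out


def knn_impute(m: pd.DataFrame, k: int = 3, metric: str = "correlation") -> pd.DataFrame:
    """Impute a protein x cell matrix; observed entries are untouched."""
    imp = CellSimilarityImputer(k=k, metric=metric)
    filled = imp.fit(m.T.to_numpy(float)).transform(m.T.to_numpy(float))
    return pd.DataFrame(filled.T, index=m.index, columns=m.columns)
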