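"""Two-cluster partition of cells in PC space, and protein-set scoring."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = ["TwoMeansClusters", "ClusterAssignment", "cluster_two", "set_score"]


@dataclass
class ClusterAssignment:
    labels: pd.Series           # cell_id -> "A" / "B"
    method: str

    def cells(self, which: str) -> pd.Index:
        return self.labels.index[self.labels == which]


class TwoMeansClusters(BaseEstimator):
    """Seeded 2-means split of cells on their first two score components.

    Label "A" is the larger cluster (tie broken toward the cluster with
    greater mean first-component score).  The input rows are canonically
    sorted before k-means so the partition is invariant to cell order;
    50 seeded restarts make the optimum stable.
    """

    def __init__(self, random_state: int = 0, n_init: int = 50,
                 method: str = "kmeans"):
        self.random_state = random_state
        self.n_init = n_init
        self.method = method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)[:, :2]
        if X.shape[0] < 10:
            raise ValueError("need at least 10 cells to split")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate scores: all cells identical")
        if self.method == "pc1_sign":
            hard = X[:, 0] > np.median(X[:, 0])
            labels = hard.astype(int)
        elif self.method == "kmeans":
            order = np.lexsort((X[:, 1], X[:, 0]))
            km = KMeans(n_clusters=2, n_init=self.n_init,
                        random_state=self.random_state)
            sorted_labels = km.fit_predict(X[order])
            labels = np.empty(X.shape[0], dtype=int)
            labels[order] = sorted_labels
        else:
            raise ValueError(f"unknown method {self.method!r}")
        n0, n1 = (labels == 0).sum(), (labels == 1).sum()
        if n0 != n1:
            a = 0 if n0 > n1 else 1
        else:
            a = 0 if X[labels == 0, 0].mean() >= X[labels == 1, 0].mean() else 1
        self.labels_ = np.where(labels == a, "A", "B")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_two(pca_scores: pd.DataFrame, cells: Optional[Iterable] = None,
                random_state: int = 0, n_init: int = 50,
                method: str = "kmeans") -> ClusterAssignment:
    """Partition (a subset of) cells into clusters A and B in PC space."""
    S = pca_scores if cells is None else pca_scores.loc[list(cells)]
    est = TwoMeansClusters(random_state=random_state, n_init=n_init, method=method)
    labels = est.fit_predict(S.to_numpy(float))
    return ClusterAssignment(
        labels=pd.Series(labels, index=S.index, name="cluster"),
        method=f"{method}(n_init={n_init}, seed={random_state})",
    )


def set_score(m: pd.DataFrame, set_members: Iterable,
              groups: Optional[Mapping] = None,
              set_name: str = "set") -> tuple[pd.Series, Optional[float]]:
    """Per-cell mean abundance of a protein set, with an optional group test.

    The score for a cell is the mean of the observed member-protein
    relative levels.  When a two-group cell partition is supplied, the
    scores are compared by a two-sided Mann-Whitney test and its p-value
    is returned (otherwise None).
    """
    members = [p for p in set_members if p in m.index]
    if not members:
        raise ValueError(f"protein set {set_name!r} has no quantified member")
    score = m.loc[members].mean(axis=0, skipna=True)
    score.name = set_name
    p = None
    if groups is not None:
        g = pd.Series(groups)
        g = g[g.index.intersection(score.index)]
        levels = [lv for lv in pd.unique(g) if pd.notna(lv)]
        if len(levels) != 2:
            raise ValueError("group test requires exactly two groups")
        a = score[g.index[g == levels[0]]].dropna()
        b = score[g.index[g == levels[1]]].dropna()
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return score, p
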