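"""Integration of single-cell datasets acquired with different MS methods.

Datasets are first re-normalized to relative protein levels within their
own cells, restricted to the protein intersection, concatenated with
batch labels, and batch-corrected by a deterministic per-protein
location/scale equalization on observed values (missing entries remain
missing, and observed values are never invented).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

__all__ = ["IntegratedMatrix", "align_datasets", "batch_correct",
           "LocationScaleBatchCorrector"]


@dataclass
class IntegratedMatrix:
    matrix: pd.DataFrame          # proteins x cells (intersection only)
    batches: pd.Series            # cell_id -> batch label
    provenance: dict = field(default_factory=dict)


def _recentre(m: pd.DataFrame, tol: float = 1e-12, max_iter: int = 200) -> pd.DataFrame:
    # stops when the matrix stops changing (see quant._iterative_center)
    import warnings as _w
    X = m.to_numpy(float).copy()
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        for _ in range(max_iter):
            prev = X.copy()
            rm = np.nanmean(X, axis=1, keepdims=True)
            X = X - np.where(np.isfinite(rm), rm, 0.0)
            cm = np.nanmedian(X, axis=0, keepdims=True)
            X = X - np.where(np.isfinite(cm), cm, 0.0)
            if not (np.nanmax(np.abs(X - prev)) > tol):
                break
    return pd.DataFrame(X, index=m.index, columns=m.columns)


def align_datasets(
    ms: Sequence[pd.DataFrame],
    batch_labels: Optional[Sequence[str]] = None,
) -> IntegratedMatrix:
    """Re-center each dataset within its own cells, intersect proteins,
    and concatenate columns with batch labels (uncorrected)."""
    if len(ms) < 2:
        raise ValueError("need at least 2 datasets to integrate")
    labels = list(batch_labels) if batch_labels is not None else \
        [f"batch{i + 1}" for i in range(len(ms))]
    shared = ms[0].index
    for m in ms[1:]:
        shared = shared.intersection(m.index)
    if len(shared) == 0:
        counts = [m.shape[0] for m in ms]
        raise ValueError(f"no shared proteins across datasets (per-dataset "
                         f"protein counts: {counts})")
    parts, batches = [], []
    for m, lab in zip(ms, labels):
        cent = _recentre(m.loc[shared])
        parts.append(cent)
        batches.extend([lab] * cent.shape[1])
    matrix = pd.concat(parts, axis=1)
    return IntegratedMatrix(
        matrix=matrix,
        batches=pd.Series(batches, index=matrix.columns, name="batch"),
        provenance={"method": "align", "n_shared_proteins": int(len(shared)),
                    "batches": labels},
    )


class LocationScaleBatchCorrector(TransformerMixin, BaseEstimator):
    """Deterministic per-feature batch correction on observed values.

    For every feature, each batch's observed values are standardized by
    the batch mean and standard deviation and re-expressed on the pooled
    scale (grand mean, pooled sd), so per-feature per-batch means agree
    exactly after correction.  A batch with zero variance (or a single
    observation) for a feature gets a location-only adjustment, which is
    counted in ``n_location_only_``.
    """

    def __init__(self, min_per_batch: int = 1):
        self.min_per_batch = min_per_batch

    def fit(self, X, y=None, batches=None):
        X = np.asarray(X, dtype=float)
        if batches is None:
            raise ValueError("batches must be provided")
        batches = np.asarray(batches)
        levels = pd.unique(batches)
        if levels.size < 2:
            raise ValueError("need at least 2 batches")
        self.batch_levels_ = levels
        n_feat = X.shape[1]
        self.batch_mean_ = np.full((levels.size, n_feat), np.nan)
        self.batch_sd_ = np.full((levels.size, n_feat), np.nan)
        self.n_location_only_ = 0
        M = np.isfinite(X)
        for bi, b in enumerate(levels):
            rows = batches == b
            sub = X[rows]
            msub = M[rows]
            cnt = msub.sum(axis=0)
            with np.errstate(invalid="ignore"):
                mean = np.where(cnt > 0, np.nansum(np.where(msub, sub, 0.0), axis=0)
                                / np.maximum(cnt, 1), np.nan)
                sd = np.full(n_feat, np.nan)
                for j in range(n_feat):
                    v = sub[msub[:, j], j]
                    sd[j] = v.std(ddof=1) if v.size > 1 else np.nan
            self.batch_mean_[bi] = mean
            self.batch_sd_[bi] = sd
        # pooled targets: grand mean over all observed values, and the
        # pooled *within-batch* sd — using the combined sd instead would
        # leak the between-batch spread into the scale and break
        # idempotence
        cntall = M.sum(axis=0)
        self.grand_mean_ = np.where(cntall > 0,
                                    np.nansum(np.where(M, X, 0.0), axis=0)
                                    / np.maximum(cntall, 1), np.nan)
        counts = np.stack([(batches == b)[:, None] & M for b in levels]) \
            .sum(axis=1)                     # batch x feature observed counts
        dof = np.maximum(counts - 1, 0).astype(float)
        var = np.where(np.isfinite(self.batch_sd_), self.batch_sd_ ** 2, 0.0)
        wsum = (dof * var).sum(axis=0)
        dsum = np.where(np.isfinite(self.batch_sd_), dof, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.pooled_sd_ = np.where(dsum > 0, np.sqrt(wsum / dsum), np.nan)
        bad_sd = ~np.isfinite(self.batch_sd_) | (self.batch_sd_ <= 0)
        self.n_location_only_ = int(bad_sd.sum())
        if self.n_location_only_:
            log.info("%d (feature, batch) pairs corrected location-only "
                     "(zero variance or single observation)", self.n_location_only_)
        self.n_features_in_ = n_feat
        return self

    def transform(self, X, batches=None):
        check_is_fitted(self, "batch_mean_")
        if batches is None:
            raise ValueError("batches must be provided")
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        out = X.copy()
        for bi, b in enumerate(self.batch_levels_):
            rows = batches == b
            if not rows.any():
                continue
            mean = self.batch_mean_[bi]
            sd = self.batch_sd_[bi]
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(np.isfinite(sd) & (sd > 0)
                                 & np.isfinite(self.pooled_sd_)
                                 & (self.pooled_sd_ > 0),
                                 self.pooled_sd_ / sd, 1.0)
            shifted = (X[rows] - mean) * scale + self.grand_mean_
            out[rows] = np.where(np.isfinite(X[rows]), shifted, np.nan)
        return out

    def fit_transform(self, X, y=None, batches=None):
        return self.fit(X, batches=batches).transform(X, batches=batches)


def batch_correct(im: IntegratedMatrix) -> IntegratedMatrix:
    """Equalize per-protein batch means and pool variances.

    Proteins not observed in every batch are dropped (their count is
    recorded in provenance); observed values are adjusted, missing ones
    stay missing.
    """
    m = im.matrix
    batches = im.batches.reindex(m.columns)
    obs = m.notna()
    keep = pd.Series(True, index=m.index)
    for b in pd.unique(batches):
        keep &= obs.loc[:, batches[batches == b].index].any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("batch_correct: dropping %d proteins unobserved in some batch",
                 dropped)
    sub = m.loc[keep]
    corr = LocationScaleBatchCorrector()
    fixed = corr.fit_transform(sub.T.to_numpy(float), batches=batches.to_numpy())
    out = pd.DataFrame(fixed.T, index=sub.index, columns=sub.columns)
    prov = dict(im.provenance)
    prov.update({"method": "location_scale", "dropped_proteins": dropped,
                 "location_only_pairs": corr.n_location_only_})
    return IntegratedMatrix(matrix=out, batches=im.batches, provenance=prov)
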