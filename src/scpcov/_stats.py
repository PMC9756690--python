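"""Shared numerical primitives: pairwise-complete correlation and BH q-values.

Single-cell protein matrices are missing-not-at-random, so most correlation
structure in this package is computed on pairwise-observed values rather
than after imputation.  The masked Pearson routine below vectorises the
pairwise-complete computation with matrix products so that cell x cell
matrices for >1000 cells stay fast.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["pairwise_complete_corr", "bh_qvalues", "masked_column_corr"]


def pairwise_complete_corr(
    X: np.ndarray,
    min_shared: int = 3,
    fill: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between columns of ``X`` using pairwise-observed rows.

    Parameters
    ----------
    X
        2-D float array (features x units) with NaN marking missing values.
    min_shared
        Column pairs sharing fewer observed rows than this get correlation
        ``fill`` (the count is reported so callers can log it).
    fill
        Value used for undefined correlations (too few shared observations
        or zero variance on the shared support).

    Returns
    -------
    corr : (n_units, n_units) array, diagonal 1 where a column has any data.
    n_shared : (n_units, n_units) integer array of shared-observation counts.
    """
    X = np.asarray(X, dtype=float)
    M = np.isfinite(X)
    Mf = M.astype(float)
    Xf = np.where(M, X, 0.0)

    n = Mf.T @ Mf                     # shared counts
    sx = Xf.T @ Mf                    # sum of column i over support(i, j)
    sxx = (Xf * Xf).T @ Mf
    sxy = Xf.T @ Xf

    with np.errstate(invalid="ignore", divide="ignore"):
        num = sxy - sx * sx.T / n
        vx = sxx - sx * sx / n        # var of i on support(i, j), times n
        vy = vx.T
        corr = num / np.sqrt(vx * vy)

    bad = ~np.isfinite(corr) | (n < min_shared)
    corr = np.where(bad, fill, corr)
    np.clip(corr, -1.0, 1.0, out=corr)
    has_data = M.any(axis=0)
    idx = np.where(has_data)[0]
    corr[idx, idx] = 1.0
    return corr, n.astype(int)


def masked_column_corr(x: np.ndarray, Y: np.ndarray, min_shared: int = 3) -> np.ndarray:
    """Pearson correlation of vector ``x`` with every column of ``Y``,
    each computed on the rows where both are observed.  NaN where undefined."""
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mx = np.isfinite(x)
    out = np.full(Y.shape[1], np.nan)
    for j in range(Y.shape[1]):
        m = mx & np.isfinite(Y[:, j])
        if m.sum() < min_shared:
            continue
        a = x[m]
        b = Y[m, j]
        sa = a.std()
        sb = b.std()
        if sa == 0 or sb == 0:
            continue
        out[j] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN p-values stay NaN and do not count
    toward the number of tests."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return q
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
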