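"""Peptide-to-protein quantification: relative levels, filtering, QC.

The normalization follows the SCoPE2 convention for isobaric single-cell
data: single-cell reporter-ion intensities are first expressed relative
to the per-set reference channel (a 5-cell pool) when one exists, then
column- and row-standardized so that every cell and every peptide is on a
comparable relative scale, log2-transformed, collapsed to proteins by the
median peptide, and re-centered.  Datasets without a reference channel
(e.g. 3-plex non-isobaric acquisitions) skip the reference step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "peptide_matrix",
    "peptide_relative_matrix",
    "collapse_to_proteins",
    "normalize_scope2",
    "filter_cells_by_cv",
    "filter_min_observations",
    "qc_report",
    "QCReport",
]


def _single_cell_ids(meta: pd.DataFrame) -> pd.Index:
    drop = meta.get("is_negative_control", False) | meta.get("is_carrier", False) \
        | meta.get("is_reference", False)
    return pd.Index(meta.loc[~drop, "cell_id"])


def peptide_matrix(pep: pd.DataFrame, cells: Optional[Iterable] = None) -> pd.DataFrame:
    """Wide peptide x cell matrix of raw intensities (NaN = not observed)."""
    wide = pep.pivot(index="peptide_id", columns="cell_id", values="raw_intensity")
    wide = wide.dropna(how="all")
    if cells is not None:
        cols = [c for c in cells if c in wide.columns]
        wide = wide[cols]
    return wide


def _protein_of(pep: pd.DataFrame) -> pd.Series:
    m = pep[["peptide_id", "protein_id"]].drop_duplicates("peptide_id")
    return m.set_index("peptide_id")["protein_id"].astype(str)


def _reference_divide(wide: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Divide each single-cell column by its set's reference-channel column."""
    if "is_reference" not in meta.columns or not meta["is_reference"].any():
        return wide
    meta_i = meta.set_index("cell_id")
    refs = meta_i.index[meta_i["is_reference"]]
    ref_of_set = {meta_i.loc[r, "set_id"]: r for r in refs if r in wide.columns}
    out = wide.copy()
    for col in wide.columns:
        if col not in meta_i.index:
            continue
        sid = meta_i.loc[col, "set_id"]
        ref = ref_of_set.get(sid)
        if ref is not None and ref != col:
            out[col] = wide[col] / wide[ref]
    return out


def _iterative_center(logm: pd.DataFrame, tol: float = 1e-12,
                      max_iter: int = 200) -> pd.DataFrame:
    """Alternate row-mean and column-median centering to a fixed point.

    Row means and column medians cannot in general both be exactly zero
    (a global constant trades between them when the data are skewed), so
    the iteration stops when the matrix itself stops changing; it ends on
    the column step, making observed column medians exactly zero.
    """
    import warnings as _w
    X = logm.to_numpy(float).copy()
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN rows/cols stay NaN
        for _ in range(max_iter):
            prev = X.copy()
            rm = np.nanmean(X, axis=1, keepdims=True)
            X = X - np.where(np.isfinite(rm), rm, 0.0)
            cm = np.nanmedian(X, axis=0, keepdims=True)
            X = X - np.where(np.isfinite(cm), cm, 0.0)
            delta = np.abs(X - prev)
            if not (np.nanmax(delta) > tol):
                break
    return pd.DataFrame(X, index=logm.index, columns=logm.columns)


def collapse_to_proteins(values: pd.DataFrame, protein_of: pd.Series) -> pd.DataFrame:
    """Protein value per cell = median over its observed peptide values."""
    if values.empty:
        raise ValueError("cannot collapse an empty peptide table")
    prot = values.index.map(protein_of)
    return values.groupby(np.asarray(prot, dtype=object)).median()


def peptide_relative_matrix(
    pep: pd.DataFrame,
    meta: pd.DataFrame,
    include_negatives: bool = False,
) -> pd.DataFrame:
    """Peptide x cell matrix of log2 relative levels (normalization steps
    short of the protein collapse); used e.g. to check that a protein's
    peptides covary across single cells."""
    cells = _single_cell_ids(meta)
    if include_negatives and "is_negative_control" in meta.columns:
        cells = cells.union(meta.loc[meta["is_negative_control"], "cell_id"])
    wide = peptide_matrix(pep)
    wide = _reference_divide(wide, meta)
    wide = wide[[c for c in cells if c in wide.columns]]
    wide = wide / wide.median(axis=0)
    wide = wide.div(wide.mean(axis=1), axis=0)
    return np.log2(wide)


def normalize_scope2(
    pep: pd.DataFrame,
    meta: pd.DataFrame,
    min_peptides_per_cell: int = 2,
) -> pd.DataFrame:
    """Full normalization to a protein x cell matrix of log2 relative levels.

    Steps: reference-channel division per set (when present), per-cell
    median division, per-peptide mean division, log2, median collapse to
    proteins, then alternating column-median / row-mean re-centering.
    Cells with fewer than ``min_peptides_per_cell`` observed peptides are
    dropped with a warning.
    """
    if pep.empty:
        raise ValueError("empty peptide table")
    wide = peptide_matrix(pep)
    wide = _reference_divide(wide, meta)
    cells = [c for c in _single_cell_ids(meta) if c in wide.columns]
    wide = wide[cells]

    n_obs = wide.notna().sum(axis=0)
    thin = n_obs[n_obs < min_peptides_per_cell].index
    if len(thin):
        log.warning("dropping %d cells with < %d observed peptides",
                    len(thin), min_peptides_per_cell)
        wide = wide.drop(columns=thin)

    wide = wide / wide.median(axis=0)
    wide = wide.div(wide.mean(axis=1), axis=0)
    logm = np.log2(wide)
    prot = collapse_to_proteins(logm, _protein_of(pep))
    return _iterative_center(prot)


def filter_cells_by_cv(
    pep: pd.DataFrame,
    meta: Optional[pd.DataFrame] = None,
    threshold: float = 0.41,
    min_peptides: int = 6,
    summary: str = "median",
) -> tuple[list, pd.Series, list]:
    """Quality filter on the internal consistency of protein quantification.

    For each cell, each protein quantified by at least ``min_peptides``
    observed peptides contributes a coefficient of variation (sd / mean of
    that protein's peptide relative levels); the per-cell summary (median
    by default) is compared against ``threshold``.  Returns
    ``(kept_cell_ids, per_cell_cv, unassessable_cell_ids)`` where
    unassessable cells (no protein passing the peptide floor) are excluded
    from the filtering decision and reported separately.
    """
    df = pep.dropna(subset=["raw_intensity"]).copy()
    if meta is not None:
        keep_ids = set(_single_cell_ids(meta)) | set(
            meta.loc[meta.get("is_negative_control", pd.Series(False, index=meta.index)),
                     "cell_id"])
        df = df[df["cell_id"].astype(str).isin({str(c) for c in keep_ids})]
    # remove each cell's overall loading first (median division), so the
    # filter is exactly invariant to scaling any cell by a constant; then
    # express each peptide relative to its mean over cells
    cell_med = df.groupby("cell_id", observed=True)["raw_intensity"].transform("median")
    df["rel"] = df["raw_intensity"] / cell_med
    pep_mean = df.groupby("peptide_id", observed=True)["rel"].transform("mean")
    df["rel"] = df["rel"] / pep_mean

    g = df.groupby(["cell_id", "protein_id"], observed=True)["rel"]
    agg = g.agg(["count", "mean", "std"])
    agg = agg[agg["count"] >= min_peptides]
    cv = agg["std"] / agg["mean"]
    if summary == "median":
        per_cell = cv.groupby(level=0, observed=True).median()
    else:
        per_cell = cv.groupby(level=0, observed=True).mean()
    per_cell.name = "cv"

    all_cells = pd.Index(df["cell_id"].astype(str).unique())
    per_cell.index = per_cell.index.astype(str)
    unassessable = sorted(set(all_cells) - set(per_cell.index))
    if unassessable:
        log.warning("%d cells have no protein with >= %d peptides; "
                    "excluded from the CV decision", len(unassessable), min_peptides)
    kept = sorted(per_cell.index[per_cell <= threshold])
    return kept, per_cell, unassessable


def filter_min_observations(m: pd.DataFrame, min_obs: int = 150) -> pd.DataFrame:
    """Keep proteins observed in at least ``min_obs`` cells."""
    return m[m.notna().sum(axis=1) >= min_obs]


@dataclass
class QCReport:
    """Sample-preparation quality metrics."""

    cv_per_cell: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    delivery_efficiency: float = math.nan        # geometric-mean summary
    delivery_efficiency_mean: float = math.nan   # arithmetic mean of ratios
    delivery_n: int = 0
    negctrl_fraction_undetected: float = math.nan
    negctrl_fold: float = math.nan               # mean cell total / mean neg total
    missed_cleavage_per_cell: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    missed_cleavage_carrier: float = math.nan
    size_intensity_rho: float = math.nan
    size_intensity_rho_cbrt: float = math.nan
    size_n: int = 0
    warnings: list = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "median_cell_cv": float(self.cv_per_cell.median()) if len(self.cv_per_cell) else math.nan,
            "delivery_efficiency": self.delivery_efficiency,
            "delivery_efficiency_mean": self.delivery_efficiency_mean,
            "negctrl_fraction_undetected": self.negctrl_fraction_undetected,
            "negctrl_fold": self.negctrl_fold,
            "missed_cleavage_median": float(self.missed_cleavage_per_cell.median())
            if len(self.missed_cleavage_per_cell) else math.nan,
            "missed_cleavage_carrier": self.missed_cleavage_carrier,
            "size_intensity_rho": self.size_intensity_rho,
            "size_intensity_rho_cbrt": self.size_intensity_rho_cbrt,
        }


def qc_report(pep: pd.DataFrame, meta: pd.DataFrame,
              cv_min_peptides: int = 6) -> QCReport:
    """Compute delivery-efficiency, background, digestion and size metrics.

    Metrics whose required channel flags are absent are omitted with a
    warning rather than failing the whole report.
    """
    rep = QCReport()
    df = pep.dropna(subset=["raw_intensity"])
    meta_i = meta.set_index("cell_id")
    sc_ids = set(map(str, _single_cell_ids(meta)))

    _, rep.cv_per_cell, _ = filter_cells_by_cv(pep, meta, min_peptides=cv_min_peptides)

    # delivery efficiency vs the 5-cell reference (expected ratio 1:5)
    if meta.get("is_reference", pd.Series(False)).any():
        refs = meta_i[meta_i["is_reference"]]
        ref_of_set = dict(zip(refs["set_id"], refs.index))
        ref_rows = df[df["cell_id"].astype(str).isin(set(map(str, refs.index)))]
        ref_lookup = ref_rows.set_index(["set_id", "peptide_id"])["raw_intensity"]
        sc_rows = df[df["cell_id"].astype(str).isin(sc_ids)].copy()
        sc_rows = sc_rows[sc_rows["set_id"].astype(str).isin(set(map(str, ref_of_set)))]
        idx = pd.MultiIndex.from_frame(sc_rows[["set_id", "peptide_id"]])
        ref_vals = ref_lookup.reindex(idx).to_numpy()
        ok = np.isfinite(ref_vals)
        ratios = sc_rows["raw_intensity"].to_numpy()[ok] / ref_vals[ok] * 5.0
        if ratios.size:
            rep.delivery_efficiency = float(2.0 ** np.mean(np.log2(ratios)))
            rep.delivery_efficiency_mean = float(np.mean(ratios))
            rep.delivery_n = int(ratios.size)
    else:
        rep.warnings.append("no reference channel; delivery efficiency omitted")

    # negative controls
    if meta.get("is_negative_control", pd.Series(False)).any():
        neg_ids = set(map(str, meta_i.index[meta_i["is_negative_control"]]))
        totals = df.groupby("cell_id", observed=True)["raw_intensity"].sum()
        counts = df.groupby("cell_id", observed=True)["raw_intensity"].size()
        totals.index = totals.index.astype(str)
        counts.index = counts.index.astype(str)
        cells_tot = totals[totals.index.isin(sc_ids)]
        neg_tot = totals.reindex(sorted(neg_ids)).fillna(0.0)
        n_pep_total = df["peptide_id"].astype(str).nunique()
        neg_counts = counts.reindex(sorted(neg_ids)).fillna(0)
        rep.negctrl_fraction_undetected = float(1.0 - neg_counts.mean() / n_pep_total)
        if neg_tot.mean() > 0:
            rep.negctrl_fold = float(cells_tot.mean() / neg_tot.mean())
    else:
        rep.warnings.append("no negative controls; background metrics omitted")

    # missed-cleavage ratio: summed missed / fully-cleaved intensity within a
    # cell, over proteins where both forms are observed in that cell
    if (df["n_missed_cleavages"] > 0).any():
        # pair each missed-cleaved peptide with its fully cleaved
        # counterpart in the same cell (trailing-"mc" id convention by
        # default; pass an explicit parent map via the peptide ids to
        # override)
        mcdf = df[df["n_missed_cleavages"] > 0][
            ["peptide_id", "cell_id", "raw_intensity"]].copy()
        mcdf["parent"] = mcdf["peptide_id"].astype(str).str.replace(
            r"mc$", "", regex=True)
        fulldf = df[df["n_missed_cleavages"] == 0][
            ["peptide_id", "cell_id", "raw_intensity"]].copy()
        fulldf["peptide_id"] = fulldf["peptide_id"].astype(str)
        mcdf["cell_id"] = mcdf["cell_id"].astype(str)
        fulldf["cell_id"] = fulldf["cell_id"].astype(str)
        merged = mcdf.merge(fulldf, left_on=["parent", "cell_id"],
                            right_on=["peptide_id", "cell_id"],
                            suffixes=("_mc", "_full"))
        if len(merged):
            cell_ratio = merged.groupby("cell_id")[
                ["raw_intensity_mc", "raw_intensity_full"]].sum()
            ratio = cell_ratio["raw_intensity_mc"] / cell_ratio["raw_intensity_full"]
            ratio.index = ratio.index.astype(str)
            rep.missed_cleavage_per_cell = ratio[ratio.index.isin(sc_ids)]
            car_ids = set(map(str, meta_i.index[meta_i.get("is_carrier", False)])) \
                if "is_carrier" in meta.columns else set()
            car = ratio[ratio.index.isin(car_ids)]
            if len(car):
                rep.missed_cleavage_carrier = float(car.mean())

    # cell size versus signal
    dia = meta_i["diameter"] if "diameter" in meta_i.columns else pd.Series(dtype=float)
    dia = dia.dropna()
    dia.index = dia.index.astype(str)
    if len(dia) >= 3:
        # per-cell protein content summarized by the median observed RI:
        # the linear-scale mean is dominated by the few brightest peptides
        # and is an unstable location estimate over several orders of
        # magnitude of dynamic range
        cell_ri = df.groupby("cell_id", observed=True)["raw_intensity"].median()
        cell_ri.index = cell_ri.index.astype(str)
        common = dia.index.intersection(cell_ri.index)
        if len(common) >= 3:
            d = dia[common].to_numpy()
            i = cell_ri[common].to_numpy()
            rep.size_intensity_rho = float(stats.pearsonr(d, i)[0])
            rep.size_intensity_rho_cbrt = float(stats.pearsonr(d, np.cbrt(i))[0])
            rep.size_n = int(len(common))
    else:
        rep.warnings.append("no diameters; size-intensity correlation omitted")
    return rep
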