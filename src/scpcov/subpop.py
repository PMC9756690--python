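"""Melanoma subpopulation analysis: enrichment, differential proteins,
phase composition, protein concentration versus cell size, within-cluster
covariation and the gradient embedding.

Every statistic here uses observed values only — no imputation — because
imputed entries would import between-cell correlation structure that the
tests are trying to measure.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from ._stats import bh_qvalues, pairwise_complete_corr
from .cluster import ClusterAssignment
from .pca import PCAResult, corr_pca

log = logging.getLogger(__name__)

__all__ = [
    "psea", "diff_kw", "phase_by_cluster", "concentration_analysis",
    "within_cluster_corr", "pair_correlation", "gradient_pca",
]


def _cluster_series(clusters) -> pd.Series:
    if isinstance(clusters, ClusterAssignment):
        return clusters.labels
    return pd.Series(clusters)


def psea(
    m: pd.DataFrame,
    clusters,
    gene_sets: Mapping[str, Sequence],
    min_set: int = 4,
    completeness: float = 0.8,
    fdr: float = 0.01,
    min_effect: float = 0.5,
) -> pd.DataFrame:
    """Protein set enrichment between clusters A and B.

    Pooled member-protein relative levels (observed values only) are
    compared between clusters by a two-sided t-test; the effect is the
    difference of cluster means on the log2 scale.  A set is testable
    only if >= ``min_set`` member proteins are quantified and the data
    completeness of the pooled member block exceeds ``completeness`` in
    each cluster.  Reported significant = q < ``fdr`` and
    |effect| >= log2(1 + ``min_effect``) — an effect size > 50% at the
    default.
    """
    cl = _cluster_series(clusters)
    cells_a = [c for c in cl.index[cl == "A"] if c in m.columns]
    cells_b = [c for c in cl.index[cl == "B"] if c in m.columns]
    rows, skipped = [], {}
    for name, members in gene_sets.items():
        present = [p for p in members if p in m.index]
        if len(present) < min_set:
            skipped[name] = "fewer than min_set quantified members"
            continue
        A = m.loc[present, cells_a].to_numpy(float)
        B = m.loc[present, cells_b].to_numpy(float)
        comp_a = np.isfinite(A).mean() if A.size else 0.0
        comp_b = np.isfinite(B).mean() if B.size else 0.0
        if comp_a < completeness or comp_b < completeness:
            skipped[name] = "completeness floor not met"
            continue
        a = A[np.isfinite(A)]
        b = B[np.isfinite(B)]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"set": name, "n_members": len(present),
                     "effect": float(b.mean() - a.mean()),  # B minus A, log2
                     "t": float(t), "p": float(p),
                     "completeness_A": float(comp_a), "completeness_B": float(comp_b)})
    for name, why in skipped.items():
        log.info("PSEA: set %s skipped (%s)", name, why)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("set")
        out["q"] = bh_qvalues(out["p"].to_numpy())
        out["significant"] = (out["q"] < fdr) & \
            (out["effect"].abs() >= math.log2(1.0 + min_effect))
    out.attrs["skipped"] = skipped
    return out


def diff_kw(
    m: pd.DataFrame,
    clusters,
    min_frac_obs: float = 0.5,
    fdr: float = 0.01,
    min_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Per-protein Kruskal-Wallis differential abundance between clusters.

    A protein qualifies when observed in at least ``min_frac_obs`` of the
    analyzed cells; significance requires q < ``fdr`` and an absolute
    difference of cluster medians of at least ``min_log2fc`` (the
    "2-fold-or-more" rule at the default).
    """
    cl = _cluster_series(clusters)
    cells = [c for c in cl.index if c in m.columns]
    cl = cl[cells]
    ca = [c for c in cells if cl[c] == "A"]
    cb = [c for c in cells if cl[c] == "B"]
    X = m[cells]
    frac = X.notna().mean(axis=1)
    rows = []
    for prot in X.index[frac >= min_frac_obs]:
        a = X.loc[prot, ca].dropna().to_numpy(float)
        b = X.loc[prot, cb].dropna().to_numpy(float)
        if a.size == 0 or b.size == 0:
            rows.append({"protein_id": prot, "median_A": np.nan, "median_B": np.nan,
                         "effect": np.nan, "H": np.nan, "p": np.nan,
                         "n_A": a.size, "n_B": b.size})
            continue
        try:
            H, p = stats.kruskal(a, b)
        except ValueError:      # all values identical
            H, p = 0.0, 1.0
        rows.append({"protein_id": prot,
                     "median_A": float(np.median(a)), "median_B": float(np.median(b)),
                     "effect": float(np.median(b) - np.median(a)),
                     "H": float(H), "p": float(p), "n_A": a.size, "n_B": b.size})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("protein_id")
        out["q"] = bh_qvalues(out["p"].to_numpy())
        out["significant"] = (out["q"] < fdr) & (out["effect"].abs() >= min_log2fc)
    return out


def phase_by_cluster(phases: pd.Series, clusters) -> dict:
    """Phase composition per cluster with a chi-squared independence test."""
    cl = _cluster_series(clusters)
    common = phases.index.intersection(cl.index)
    ph = phases[common]
    cl = cl[common]
    ok = (ph != "NA") & (cl != "NA") & ph.notna() & cl.notna()
    tab = pd.crosstab(cl[ok], ph[ok])
    if tab.shape[0] == 0 or (tab.sum(axis=1) == 0).any():
        raise ValueError("empty cluster in phase composition")
    frac = tab.div(tab.sum(axis=1), axis=0)
    if tab.shape[0] >= 2 and tab.shape[1] >= 2:
        chi2, p, _, _ = stats.chi2_contingency(tab)
    else:
        chi2, p = np.nan, np.nan
    return {"counts": tab, "fractions": frac, "chi2": float(chi2), "p": float(p)}


def concentration_analysis(
    pep: pd.DataFrame,
    meta: pd.DataFrame,
    clusters,
) -> dict:
    """Total protein concentration per unit cell volume, by cluster.

    Volume is the sphere implied by the measured diameter, (pi/6) d^3;
    concentration = summed raw reporter-ion signal / volume.  Clusters
    are compared by a two-sided Mann-Whitney test, and the size-intensity
    regression offset per cluster (common slope of log2 total signal on
    log2 volume, cluster-specific intercepts) is reported.
    """
    cl = _cluster_series(clusters)
    totals = pep.dropna(subset=["raw_intensity"]) \
        .groupby("cell_id", observed=True)["raw_intensity"].sum()
    totals.index = totals.index.astype(str)
    dia = meta.set_index("cell_id")["diameter"]
    dia.index = dia.index.astype(str)

    rows = []
    for cell in cl.index:
        d = dia.get(str(cell), np.nan)
        t = totals.get(str(cell), np.nan)
        if not np.isfinite(d) or d <= 0:
            log.info("cell %s excluded from concentration analysis "
                     "(missing/nonpositive diameter)", cell)
            continue
        if not np.isfinite(t):
            continue
        vol = math.pi / 6.0 * d ** 3
        rows.append({"cell_id": cell, "diameter": float(d), "volume": vol,
                     "total_signal": float(t), "concentration": float(t) / vol,
                     "cluster": cl[cell]})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no cells with diameters and signal")
    a = table.loc[table["cluster"] == "A", "concentration"]
    b = table.loc[table["cluster"] == "B", "concentration"]
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue) \
        if len(a) and len(b) else np.nan
    ratio = float(b.median() / a.median()) if len(a) and len(b) else np.nan

    # common-slope regression of log2 signal on log2 volume with
    # cluster-specific intercepts
    offsets = {}
    if len(a) and len(b):
        y = np.log2(table["total_signal"].to_numpy())
        x = np.log2(table["volume"].to_numpy())
        isb = (table["cluster"] == "B").to_numpy(float)
        Xd = np.column_stack([x, np.ones_like(x), isb])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        offsets = {"slope": float(beta[0]), "intercept_A": float(beta[1]),
                   "offset_B": float(beta[2])}
    return {"table": table, "p": p, "concentration_ratio_BA": ratio,
            "regression": offsets}


def pair_correlation(m: pd.DataFrame, prot1, prot2) -> dict:
    """Covariation of one protein pair across cells (observed values):
    Pearson rho is reported, the p-value comes from the Spearman test."""
    a = m.loc[prot1].to_numpy(float)
    b = m.loc[prot2].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return {"rho": np.nan, "p": np.nan, "n": int(ok.sum())}
    rho = float(stats.pearsonr(a[ok], b[ok])[0])
    p = float(stats.spearmanr(a[ok], b[ok])[1])
    return {"rho": rho, "p": p, "n": int(ok.sum())}


def within_cluster_corr(
    m: pd.DataFrame,
    clusters,
    proteins: Sequence,
    restrict: str = "A",
    min_pairs: int = 5,
    annotation: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Pairwise-observed Pearson correlations among selected proteins,
    computed only from cells of the restricted cluster.

    Rows are ordered by functional annotation (when given) and then by
    average-linkage hierarchical clustering on correlation distance, so
    heatmaps are reproducible.
    """
    cl = _cluster_series(clusters)
    cells = [c for c in cl.index[cl == restrict] if c in m.columns]
    if len(cells) < 10:
        raise ValueError(f"cluster {restrict} has {len(cells)} cells; need >= 10")
    prots = [p for p in proteins if p in m.index]
    sub = m.loc[prots, cells]
    C, n = pairwise_complete_corr(sub.T.to_numpy(float), min_shared=min_pairs,
                                  fill=np.nan)
    C[n < min_pairs] = np.nan
    np.fill_diagonal(C, 1.0)
    corr = pd.DataFrame(C, index=prots, columns=prots)

    # deterministic leaf order on correlation distance
    Cfill = np.where(np.isfinite(C), C, 0.0)
    np.fill_diagonal(Cfill, 1.0)
    dist = 1.0 - Cfill
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(dist, checks=False)))
    ordered = [prots[i] for i in order]
    if annotation:
        ann = {p: annotation.get(p, "zzz_unannotated") for p in ordered}
        ordered = sorted(ordered, key=lambda p: (ann[p], order.tolist().index(prots.index(p))))
    return corr.loc[ordered, ordered]


def gradient_pca(
    m_integrated: pd.DataFrame,
    diff_proteins: Sequence,
    cluster_markers_a: Sequence,
    cluster_markers_b: Sequence,
    n_components: int = 2,
) -> dict:
    """Embedding of cells in the space of cluster-differential proteins.

    The embedding is the correlation-matrix PCA restricted to the
    differential proteins; per-cell means of the cluster-A-up and
    cluster-B-up marker proteins (observed values) are returned for
    coloring, together with the Spearman association of each with the
    first component.
    """
    prots = [p for p in diff_proteins if p in m_integrated.index]
    if len(prots) < 10:
        raise ValueError(f"only {len(prots)} differential proteins present; need >= 10")
    res: PCAResult = corr_pca(m_integrated.loc[prots], n_components=n_components)
    ma = [p for p in cluster_markers_a if p in m_integrated.index]
    mb = [p for p in cluster_markers_b if p in m_integrated.index]
    mean_a = m_integrated.loc[ma].mean(axis=0, skipna=True) if ma else \
        pd.Series(np.nan, index=m_integrated.columns)
    mean_b = m_integrated.loc[mb].mean(axis=0, skipna=True) if mb else \
        pd.Series(np.nan, index=m_integrated.columns)
    pc1 = res.scores.iloc[:, 0]

    def _sp(x: pd.Series):
        ok = np.isfinite(x.to_numpy(float)) & np.isfinite(pc1.reindex(x.index).to_numpy(float))
        if ok.sum() < 3:
            return np.nan, np.nan
        r, p = stats.spearmanr(pc1.reindex(x.index)[ok], x[ok])
        return float(r), float(p)

    rho_a, p_a = _sp(mean_a)
    rho_b, p_b = _sp(mean_b)
    marker_means = pd.DataFrame({"mean_A_markers": mean_a, "mean_B_markers": mean_b})
    return {"pca": res, "marker_means": marker_means,
            "spearman_pc1_A": rho_a, "p_A": p_a,
            "spearman_pc1_B": rho_b, "p_B": p_b}
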