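"""Cell-division-cycle analysis: bulk differential proteins, phase-marker
construction and cross-validation, marker-protein covariation, set-level
covariation ANOVA with split-half reproducibility, and greedy phase
assignment under phase quotas.

Phase markers are averaged profiles of a few proteins peaking in the same
phase.  They are constructed combinatorially: all 2- and 3-protein
combinations of bulk-nominated candidates are averaged per cell, and per
phase the two disjoint combinations with the highest mutual correlation
are selected subject to negative correlation against the other phases'
selected combinations.  The union of the two winning combinations forms
the phase marker.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, pairwise_complete_corr
from .config import ConfigError

log = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2")

__all__ = [
    "PhaseMarkerSet", "MarkerPattern",
    "bulk_normalize", "bulk_phase_anova", "select_candidates",
    "construct_phase_markers", "crossvalidate_markers",
    "correlate_to_markers", "marker_correlation_matrix",
    "set_covariation_anova", "split_half_reproducibility",
    "assign_phases_greedy", "greedy_assign", "bulk_covariation_overlap",
]


# --------------------------------------------------------------- bulk stage

def bulk_normalize(bulk: pd.DataFrame) -> pd.DataFrame:
    """Peptide x sample matrix of log2 relative intensities.

    Each sample is normalized to its median (loading), then each peptide
    to its mean across samples (relative level)."""
    wide = bulk.pivot(index="peptide_id", columns="sample_id", values="raw_intensity")
    wide = wide / wide.median(axis=0)
    wide = wide.div(wide.mean(axis=1), axis=0)
    return np.log2(wide)


def bulk_phase_anova(bulk: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of normalized peptide intensities across CDC phases.

    All peptides of a protein group, from every cell type, are pooled and
    compared across phases; q-values are Benjamini-Hochberg across
    proteins.  Also reports per-phase means, each protein's peak phase
    and its fold change (peak minus the mean of the other phases, log2).
    """
    phases_present = [p for p in PHASES if (bulk["phase"] == p).any()]
    if len(phases_present) < 2:
        raise ValueError("bulk table contains a single phase; ANOVA undefined")
    norm = bulk_normalize(bulk)
    phase_of = bulk.drop_duplicates("sample_id").set_index("sample_id")["phase"]
    prot_of = bulk.drop_duplicates("peptide_id").set_index("peptide_id")["protein_id"]

    rows = []
    sample_phase = phase_of.reindex(norm.columns).to_numpy()
    values = norm.to_numpy(float)
    prots = prot_of.reindex(norm.index).to_numpy()
    for prot in pd.unique(prots):
        sub = values[prots == prot]
        groups = []
        means = {}
        for ph in PHASES:
            g = sub[:, sample_phase == ph].ravel()
            g = g[np.isfinite(g)]
            means[ph] = float(g.mean()) if g.size else np.nan
            if g.size >= 2:
                groups.append(g)
        if len(groups) >= 2:
            F, p = stats.f_oneway(*groups)
        else:
            F, p = np.nan, np.nan
        finite = {k: v for k, v in means.items() if np.isfinite(v)}
        if finite:
            peak = max(finite, key=finite.get)
            others = [v for k, v in finite.items() if k != peak]
            fold = finite[peak] - float(np.mean(others)) if others else np.nan
        else:
            peak, fold = "NA", np.nan
        rows.append({"protein_id": prot, "F": F, "p": p,
                     "mean_G1": means["G1"], "mean_S": means["S"],
                     "mean_G2": means["G2"], "peak_phase": peak, "fold": fold,
                     "n_obs": int(np.isfinite(sub).sum())})
    out = pd.DataFrame(rows).set_index("protein_id")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def select_candidates(
    anova: pd.DataFrame,
    pep_rel: pd.DataFrame,
    protein_of: pd.Series,
    q_threshold: float = 0.01,
    top: int = 10,
    min_peptides: int = 2,
    min_shared: int = 10,
) -> dict:
    """Nominate per-phase marker candidates.

    A candidate must be significant in the bulk phase ANOVA and have at
    least ``min_peptides`` peptides whose single-cell relative levels are
    positively correlated (median pairwise Pearson > 0); the ``top``
    candidates per peak phase are ranked by bulk fold change.
    """
    sig = anova[(anova["q"] < q_threshold) & anova["fold"].notna()]
    pep_prot = pep_rel.index.map(protein_of)
    candidates: dict[str, list] = {}
    for ph in PHASES:
        pool = sig[sig["peak_phase"] == ph].sort_values("fold", ascending=False)
        chosen = []
        for prot in pool.index:
            sub = pep_rel.loc[np.asarray(pep_prot) == prot]
            if sub.shape[0] < min_peptides:
                continue
            corr, _ = pairwise_complete_corr(sub.to_numpy(float).T,
                                             min_shared=min_shared, fill=np.nan)
            iu = np.triu_indices(corr.shape[0], k=1)
            vals = corr[iu]
            vals = vals[np.isfinite(vals)]
            if vals.size and np.median(vals) > 0:
                chosen.append(prot)
            if len(chosen) >= top:
                break
        candidates[ph] = chosen
    return candidates


# ------------------------------------------------------ marker construction

@dataclass
class PhaseMarkerSet:
    """Selected marker proteins per phase plus provenance."""

    proteins: dict                       # phase -> list of protein ids
    groups: dict                         # phase -> (combo1, combo2) tuples
    provenance: dict = field(default_factory=dict)
    training_cell_type: str = "NA"

    def vectors_for(self, m: pd.DataFrame) -> pd.DataFrame:
        """Per-cell marker value: mean of observed selected-protein levels."""
        cols = {}
        for ph, prots in self.proteins.items():
            present = [p for p in prots if p in m.index]
            cols[ph] = m.loc[present].mean(axis=0, skipna=True) if present \
                else pd.Series(np.nan, index=m.columns)
        return pd.DataFrame(cols)

    def group_vectors_for(self, m: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for ph in self.groups:
            for k, combo in enumerate(self.groups[ph], start=1):
                present = [p for p in combo if p in m.index]
                cols[f"{ph}_{k}"] = m.loc[present].mean(axis=0, skipna=True) \
                    if present else pd.Series(np.nan, index=m.columns)
        return pd.DataFrame(cols)


def _combo_vectors(m: pd.DataFrame, candidates: Sequence,
                   combo_sizes: Iterable[int]) -> tuple[list, np.ndarray]:
    present = [p for p in candidates if p in m.index]
    combos = []
    for k in combo_sizes:
        combos.extend(itertools.combinations(present, k))
    if not combos:
        return [], np.empty((m.shape[1], 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells -> NaN
        V = np.stack([np.nanmean(m.loc[list(c)].to_numpy(float), axis=0)
                      for c in combos], axis=1)
    return combos, V


def construct_phase_markers(
    m: pd.DataFrame,
    candidates: Mapping[str, Sequence],
    combo_sizes: Iterable[int] = (2, 3),
    training_cell_type: str = "NA",
    min_shared: int = 10,
) -> PhaseMarkerSet:
    """Combinatorial phase-marker search on a protein x cell matrix.

    Per phase, every 2- and 3-subset of candidates is averaged per cell;
    the two disjoint subsets with the highest mutual Pearson correlation
    are selected, subject to every correlation against the previously
    selected phases' subsets being negative.  When no pair satisfies the
    sign constraints the objective relaxes to (within-phase correlation
    minus the worst cross-phase correlation) and the phase is flagged.
    """
    phases = [ph for ph in PHASES if ph in candidates]
    for ph in phases:
        if len([p for p in candidates[ph] if p in m.index]) < 2:
            raise ValueError(f"phase {ph} needs at least 2 quantified candidates")

    all_combos: list[tuple[str, tuple]] = []
    vec_list = []
    for ph in phases:
        combos, V = _combo_vectors(m, candidates[ph], combo_sizes)
        for c, v in zip(combos, V.T):
            all_combos.append((ph, c))
            vec_list.append(v)
    V = np.stack(vec_list, axis=1)                       # cells x combos
    C, _ = pairwise_complete_corr(V, min_shared=min_shared, fill=np.nan)

    idx_by_phase = {ph: [i for i, (p, _) in enumerate(all_combos) if p == ph]
                    for ph in phases}
    selected: dict[str, tuple] = {}
    selected_idx: dict[str, tuple] = {}
    provenance: dict = {"combo_scores": {}, "relaxed": []}

    for ph in phases:
        ids = idx_by_phase[ph]
        prev = [i for p2 in selected_idx for i in selected_idx[p2]]
        best_feasible = None
        best_relaxed = None
        records = []
        for a, b in itertools.combinations(ids, 2):
            ca, cb = all_combos[a][1], all_combos[b][1]
            if set(ca) & set(cb):
                continue
            within = C[a, b]
            if not np.isfinite(within):
                continue
            cross = [C[a, j] for j in prev] + [C[b, j] for j in prev]
            cross = [x for x in cross if np.isfinite(x)]
            max_cross = max(cross) if cross else -np.inf
            feasible = all(x < 0 for x in cross)
            records.append((ca, cb, float(within),
                            float(max_cross) if cross else np.nan, feasible))
            if feasible and (best_feasible is None or within > best_feasible[0]):
                best_feasible = (within, a, b)
            score = within - (max_cross if cross else 0.0)
            if best_relaxed is None or score > best_relaxed[0]:
                best_relaxed = (score, a, b)
        if best_feasible is not None:
            _, a, b = best_feasible
        elif best_relaxed is not None:
            _, a, b = best_relaxed
            provenance["relaxed"].append(ph)
            log.warning("phase %s: no combo pair with negative cross-phase "
                        "correlations; relaxed objective used", ph)
        else:
            raise ValueError(f"phase {ph}: no valid disjoint combo pair")
        selected[ph] = (all_combos[a][1], all_combos[b][1])
        selected_idx[ph] = (a, b)
        provenance["combo_scores"][ph] = pd.DataFrame(
            records, columns=["combo1", "combo2", "within", "max_cross", "feasible"])

    proteins = {ph: sorted(set(selected[ph][0]) | set(selected[ph][1]))
                for ph in phases}
    return PhaseMarkerSet(proteins=proteins, groups=selected,
                          provenance=provenance,
                          training_cell_type=training_cell_type)


# ------------------------------------------------------- cross-validation

@dataclass
class MarkerPattern:
    train_corr: pd.DataFrame     # 6x6 marker-group correlations, training cells
    test_corr: pd.DataFrame      # same groups on the held-out cell type
    rho: float                   # agreement of the two off-diagonal patterns
    p: float

    @property
    def expected_sign(self) -> pd.DataFrame:
        names = self.train_corr.index
        sign = pd.DataFrame(-1.0, index=names, columns=names)
        for a in names:
            for b in names:
                if a.split("_")[0] == b.split("_")[0]:
                    sign.loc[a, b] = 1.0
        return sign


def _group_corr(markers: PhaseMarkerSet, m: pd.DataFrame,
                min_cells: int = 10) -> pd.DataFrame:
    G = markers.group_vectors_for(m)
    n_obs = G.notna().sum(axis=0)
    thin = n_obs[n_obs < min_cells]
    if len(thin):
        raise ValueError(f"marker group(s) {list(thin.index)} observed in "
                         f"fewer than {min_cells} cells")
    C, _ = pairwise_complete_corr(G.to_numpy(float), min_shared=3, fill=np.nan)
    return pd.DataFrame(C, index=G.columns, columns=G.columns)


def crossvalidate_markers(markers: PhaseMarkerSet, m_train: pd.DataFrame,
                          m_test: pd.DataFrame,
                          min_cells: int = 10) -> MarkerPattern:
    """Marker-group correlation pattern on training vs held-out cells.

    Agreement is the Pearson correlation between the two matrices'
    off-diagonal upper triangles (15 values for 6 groups); the diagonal
    is excluded because it is identically 1.
    """
    ct = _group_corr(markers, m_train, min_cells)
    cv = _group_corr(markers, m_test, min_cells)
    iu = np.triu_indices(ct.shape[0], k=1)
    a, b = ct.to_numpy()[iu], cv.to_numpy()[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    rho, p = stats.pearsonr(a[ok], b[ok])
    return MarkerPattern(train_corr=ct, test_corr=cv, rho=float(rho), p=float(p))


# --------------------------------------------------- covariation screening

def marker_correlation_matrix(m: pd.DataFrame, vectors: pd.DataFrame,
                              min_shared: int = 10,
                              method: str = "spearman") -> pd.DataFrame:
    """Protein x phase matrix of correlations to the marker vectors,
    each computed over pairwise-observed cells (NaN if support is thin)."""
    out = pd.DataFrame(np.nan, index=m.index, columns=vectors.columns)
    pvals = pd.DataFrame(np.nan, index=m.index, columns=vectors.columns)
    X = m.to_numpy(float)
    cells = [c for c in vectors.index if c in m.columns]
    X = m[cells].to_numpy(float)
    V = vectors.loc[cells].to_numpy(float)
    for k, ph in enumerate(vectors.columns):
        v = V[:, k]
        if np.nanstd(v) == 0:
            raise ValueError(f"marker vector {ph} is constant")
        mv = np.isfinite(v)
        for i in range(X.shape[0]):
            mask = mv & np.isfinite(X[i])
            if mask.sum() < min_shared:
                continue
            if method == "spearman":
                r, p = stats.spearmanr(X[i, mask], v[mask])
            else:
                r, p = stats.pearsonr(X[i, mask], v[mask])
            out.iloc[i, k] = r
            pvals.iloc[i, k] = p
    out.attrs["p"] = pvals
    return out


def correlate_to_markers(m: pd.DataFrame, markers: PhaseMarkerSet,
                         min_obs: int = 150, fdr: float = 0.05,
                         min_shared: int = 10,
                         vectors_from: Optional[pd.DataFrame] = None
                         ) -> pd.DataFrame:
    """Screen every sufficiently observed protein for covariation with the
    phase markers (Spearman, BH-corrected across all protein x phase tests).

    ``vectors_from`` lets the marker vectors be computed on a different
    (typically wider) matrix than the proteins being screened."""
    from .quant import filter_min_observations
    mm = filter_min_observations(m, min_obs)
    vectors = markers.vectors_for(m if vectors_from is None else vectors_from)
    vectors = vectors.loc[[c for c in m.columns if c in vectors.index]]
    corr = marker_correlation_matrix(mm, vectors, min_shared=min_shared)
    p = corr.attrs["p"]
    long = pd.DataFrame({
        "protein_id": np.repeat(mm.index, corr.shape[1]),
        "phase": list(corr.columns) * mm.shape[0],
        "rho": corr.to_numpy().ravel(),
        "p": p.to_numpy().ravel(),
    })
    long["q"] = bh_qvalues(long["p"].to_numpy())
    long["significant"] = long["q"] < fdr
    return long


def set_covariation_anova(
    ms: Mapping[str, pd.DataFrame],
    markers: Mapping[str, PhaseMarkerSet] | PhaseMarkerSet,
    gene_sets: Mapping[str, Sequence],
    min_set: int = 4,
    min_obs: int = 150,
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Set-level covariation with the CDC across two cell types.

    For each gene set: member-protein Spearman correlations to each phase
    marker within each cell type form 6 distributions, compared by
    one-way ANOVA; per-group medians are retained and a between-type
    similarity score (Pearson correlation of the two 3-phase median
    profiles) ranks shared versus cell-type-specific covariation.
    """
    from .quant import filter_min_observations
    types = list(ms)
    corr_by_type = {}
    for t in types:
        mk = markers[t] if isinstance(markers, Mapping) else markers
        mm = filter_min_observations(ms[t], min_obs)
        corr_by_type[t] = marker_correlation_matrix(mm, mk.vectors_for(ms[t]))

    rows = []
    for name, members in gene_sets.items():
        members = list(members)
        groups, medians = [], {}
        ok = True
        for t in types:
            ct = corr_by_type[t]
            present = [p2 for p2 in members if p2 in ct.index]
            sub = ct.loc[present]
            if sub.notna().any(axis=1).sum() < min_set:
                ok = False
                break
            for ph in sub.columns:
                vals = sub[ph].dropna().to_numpy()
                if fisher_z:
                    vals = np.arctanh(np.clip(vals, -0.999999, 0.999999))
                groups.append(vals)
                medians[f"med_{t}_{ph}"] = float(np.median(vals)) if vals.size else np.nan
        if not ok:
            log.info("gene set %s skipped: fewer than %d quantified members", name, min_set)
            continue
        usable = [g for g in groups if g.size >= 2]
        if len(usable) < 2:
            continue
        F, p = stats.f_oneway(*usable)
        row = {"set": name, "n_members": len(members), "F": F, "p": p, **medians}
        if len(types) == 2:
            a = [medians.get(f"med_{types[0]}_{ph}", np.nan) for ph in corr_by_type[types[0]].columns]
            b = [medians.get(f"med_{types[1]}_{ph}", np.nan) for ph in corr_by_type[types[1]].columns]
            a, b = np.asarray(a), np.asarray(b)
            if np.isfinite(a).all() and np.isfinite(b).all() and a.std() > 0 and b.std() > 0:
                row["similarity"] = float(np.corrcoef(a, b)[0, 1])
            else:
                row["similarity"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("set")
        out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def split_half_reproducibility(
    ms: Mapping[str, pd.DataFrame],
    markers: Mapping[str, PhaseMarkerSet] | PhaseMarkerSet,
    gene_sets: Mapping[str, Sequence],
    seed: int = 0,
    min_set: int = 4,
    min_obs: int = 150,
    duplicate_halves: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Reproducibility of set-level median correlations across a random
    equal split of cells within each cell type.

    Proteins are filtered on the full matrices (so both halves test the
    same features); agreement is the Pearson correlation between the two
    halves' median vectors over all (set x phase x type) entries defined
    in both.  ``duplicate_halves`` is a test mode in which both halves
    contain every cell (agreement is then exactly 1)."""
    from .quant import filter_min_observations
    rng = np.random.default_rng(seed)
    halves: list[dict] = [{}, {}]
    for t, m in ms.items():
        cells = np.array(m.columns)
        if cells.size < 40:
            raise ValueError(f"cell type {t} has {cells.size} cells; need >= 40")
        if duplicate_halves:
            halves[0][t] = m
            halves[1][t] = m
            continue
        perm = rng.permutation(cells.size)
        half = cells.size // 2
        keep = filter_min_observations(m, min_obs).index
        halves[0][t] = m.loc[keep, cells[perm[:half]]]
        halves[1][t] = m.loc[keep, cells[perm[half:]]]

    tables = [set_covariation_anova(h, markers, gene_sets, min_set=min_set,
                                    min_obs=0 if not duplicate_halves else min_obs)
              for h in halves]
    med_cols = [c for c in tables[0].columns if c.startswith("med_")]
    joined = tables[0][med_cols].join(tables[1][med_cols], how="inner",
                                      lsuffix="_h1", rsuffix="_h2")
    a = joined[[c for c in joined.columns if c.endswith("_h1")]].to_numpy().ravel()
    b = joined[[c for c in joined.columns if c.endswith("_h2")]].to_numpy().ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    rho = float(stats.pearsonr(a[ok], b[ok])[0]) if ok.sum() >= 3 else np.nan
    return tables[0], tables[1], rho


# -------------------------------------------------------- phase assignment

def greedy_assign(values: pd.DataFrame, quotas: Mapping[str, float]) -> pd.Series:
    """Quota-constrained greedy phase assignment.

    ``values`` holds one column per phase of per-cell marker abundances.
    All (cell, phase) entries are sorted by value (descending; ties broken
    by cell id then phase order) and walked once: a cell is assigned to
    an entry's phase if still unassigned and that phase's bin has room.
    Bin capacities are floor(N * quota) for the non-G1 phases with the
    remainder going to G1, so the global fractions equal the quotas up to
    flooring.  Cells missing a value for any phase are returned as "NA".
    """
    if abs(sum(quotas.values()) - 1.0) > 1e-9:
        raise ConfigError("phase quotas must sum to 1")
    phases = [ph for ph in PHASES if ph in quotas] or list(quotas)
    V = values[phases]
    eligible = V.notna().all(axis=1)
    out = pd.Series("NA", index=values.index, dtype=object, name="phase")
    cells = V.index[eligible]
    n = len(cells)
    if n == 0:
        return out
    caps = {}
    for ph in phases:
        if ph != phases[0]:
            caps[ph] = int(np.floor(n * quotas[ph]))
    caps[phases[0]] = n - sum(caps.values())

    vals = V.loc[cells].to_numpy(float)
    n_ph = len(phases)
    flat_val = vals.ravel()
    cell_rank = np.repeat(np.argsort(np.argsort(np.asarray(cells, dtype=object),
                                                kind="stable"), kind="stable"), n_ph)
    phase_ord = np.tile(np.arange(n_ph), n)
    order = np.lexsort((phase_ord, cell_rank, -flat_val))

    assigned: dict = {}
    fill = dict.fromkeys(phases, 0)
    for k in order:
        ci = k // n_ph
        ph = phases[k % n_ph]
        cell = cells[ci]
        if cell in assigned or fill[ph] >= caps[ph]:
            continue
        assigned[cell] = ph
        fill[ph] += 1
    out.loc[list(assigned)] = list(assigned.values())
    return out


def assign_phases_greedy(m: pd.DataFrame, markers: PhaseMarkerSet,
                         quotas: Optional[Mapping[str, float]] = None) -> pd.Series:
    """Assign each cell to G1/S/G2 from its phase-marker abundances."""
    quotas = dict(quotas) if quotas else {"G1": 0.50, "S": 0.25, "G2": 0.25}
    vectors = markers.vectors_for(m)
    return greedy_assign(vectors, quotas)


def bulk_covariation_overlap(sig_covariation: Iterable, sig_bulk: Iterable,
                             universe: Iterable) -> tuple[float, np.ndarray]:
    """One-sided Fisher exact test for overlap of two significant-set lists
    drawn from a common universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty set universe")
    a = set(sig_covariation) & universe
    b = set(sig_bulk) & universe
    both = len(a & b)
    table = np.array([[both, len(a) - both],
                      [len(b) - both, len(universe) - len(a | b)]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p), table
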