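"""End-to-end orchestration: simulate -> normalize/QC -> embed/cluster ->
cell-cycle analysis -> subpopulation analysis -> integration.

``run_pipeline`` executes the stages in dependency order from a single
:class:`~scpcov.config.PipelineConfig` and returns a machine-readable
report; identical configuration and seeds give identical numeric results
(wall time excluded).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cdc, quant, subpop as subpop_mod
from .cluster import cluster_two
from .config import PipelineConfig
from .impute import knn_impute
from .integrate import align_datasets, batch_correct
from .pca import weighted_pca
from .sim import make_gene_sets, simulate_bulk_sorted, simulate_dataset

log = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)   # in-memory, not serialized
    error: Optional[str] = None
    elapsed_s: float = 0.0

    def to_dict(self) -> dict:
        return {"config": self.config, "stages": self.stages,
                "dropped": self.dropped, "metrics": self.metrics,
                "error": self.error, "elapsed_s": self.elapsed_s}

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, pd.Index)):
        return list(x)
    return str(x)


def _subset_pep(pep: pd.DataFrame, cells: set) -> pd.DataFrame:
    out = pep[pep["cell_id"].astype(str).isin({str(c) for c in cells})].copy()
    for col in ("peptide_id", "protein_id", "cell_id", "set_id"):
        if isinstance(out[col].dtype, pd.CategoricalDtype):
            out[col] = out[col].cat.remove_unused_categories()
    return out


def run_pipeline(config: Optional[PipelineConfig] = None) -> RunReport:
    cfg = config if config is not None else PipelineConfig()
    t0 = time.time()
    report = RunReport(config=cfg.to_dict())
    try:
        _run(cfg, report)
    except Exception as exc:   # report written up to the failing stage
        log.exception("pipeline stage failed")
        report.error = f"{type(exc).__name__}: {exc}"
    report.elapsed_s = time.time() - t0
    if cfg.out_dir:
        report.write(Path(cfg.out_dir) / "run_report.json")
    return report


def _run(cfg: PipelineConfig, report: RunReport) -> None:
    stages = set(cfg.stages)

    # ------------------------------------------------------------ simulate
    sim = simulate_dataset(cfg.sim)
    truth = sim.truth.set_index("cell_id")
    gene_sets = make_gene_sets(sim.protein_truth, seed=cfg.seed)
    report.stages["simulate"] = {
        "n_single_cells": int(len(sim.single_cells)),
        "n_negative_controls": int(sim.cell_meta["is_negative_control"].sum()),
        "n_proteins": int(sim.protein_expected.shape[0]),
        "n_peptide_rows": int(len(sim.peptide_table)),
        "n_gene_sets": len(gene_sets),
    }
    report.artifacts.update({"sim": sim, "gene_sets": gene_sets})
    if stages == {"simulate"}:
        return

    meta = sim.cell_meta
    pep = sim.peptide_table

    # ----------------------------------------------------------- normalize
    kept, cv, unassessable = quant.filter_cells_by_cv(
        pep, meta, threshold=cfg.cv_threshold, min_peptides=cfg.cv_min_peptides)
    sc_ids = set(map(str, sim.single_cells))
    kept_sc = [c for c in kept if c in sc_ids]
    report.dropped["cv_filter"] = {
        "n_failed": int(len(cv) - len(kept)),
        "n_unassessable": len(unassessable),
        "reason": f"median protein CV > {cfg.cv_threshold}",
    }

    batch_of = truth["batch"]
    cells_b1 = [c for c in kept_sc if batch_of.get(c) == "batch1"]
    cells_b2 = [c for c in kept_sc if batch_of.get(c) == "batch2"]
    m1 = quant.normalize_scope2(_subset_pep(pep, set(cells_b1) | _aux_ids(meta)), meta)
    m2 = quant.normalize_scope2(_subset_pep(pep, set(cells_b2)), meta) \
        if cells_b2 else pd.DataFrame()
    report.stages["normalize"] = {
        "batch1_shape": list(m1.shape), "batch2_shape": list(m2.shape),
        "cells_kept": len(kept_sc),
    }
    report.artifacts.update({"m1": m1, "m2": m2, "cells_b1": cells_b1,
                             "cells_b2": cells_b2})

    # ------------------------------------------------------------------ qc
    if "qc" in stages:
        qc = quant.qc_report(pep, meta, cv_min_peptides=cfg.cv_min_peptides)
        report.stages["qc"] = qc.summary()
        report.artifacts["qc"] = qc

    # --------------------------------------------------------------- embed
    ctype = truth["cell_type"]
    mel1 = [c for c in m1.columns if ctype.get(c) == "melanoma"]
    mono1 = [c for c in m1.columns if ctype.get(c) == "monocyte"]
    m1f = quant.filter_min_observations(m1, cfg.min_obs)
    m1_imp = knn_impute(m1f, k=cfg.knn_k)
    pca_all = weighted_pca(m1_imp, n_components=2)
    clusters1 = None
    if mel1:
        pca_mel = weighted_pca(m1_imp[mel1], n_components=2)
        clusters1 = cluster_two(pca_mel.scores, random_state=cfg.seed)
    report.stages["embed"] = {
        "explained_variance": [float(v) for v in pca_all.explained_variance_fraction],
        "cluster_sizes": {k: int(v) for k, v in
                          clusters1.labels.value_counts().items()}
        if clusters1 else {},
    }
    report.artifacts.update({"pca_all": pca_all, "clusters1": clusters1,
                             "m1_imp": m1_imp})
    if clusters1 is not None:
        report.metrics["clusterB_recall_batch1"] = _recall_b(clusters1.labels, truth)

    # ----------------------------------------------------------------- cdc
    markers = None
    phases = None
    if "cdc" in stages:
        bulk = simulate_bulk_sorted(cfg.sim, n_replicates=3)
        anova = cdc.bulk_phase_anova(bulk)
        pep_rel = quant.peptide_relative_matrix(
            _subset_pep(pep, set(cells_b1) | _aux_ids(meta)), meta)
        prot_of = pep.drop_duplicates("peptide_id") \
            .set_index("peptide_id")["protein_id"].astype(str)
        candidates = cdc.select_candidates(anova, pep_rel, prot_of,
                                           q_threshold=cfg.bulk_fdr,
                                           top=cfg.candidates_per_phase)
        markers = cdc.construct_phase_markers(m1[mono1] if mono1 else m1,
                                              candidates,
                                              training_cell_type="monocyte")
        pattern = cdc.crossvalidate_markers(markers, m1[mono1], m1[mel1]) \
            if (mono1 and mel1) else None
        phases = cdc.assign_phases_greedy(m1, markers, quotas=cfg.quotas)
        acc = _phase_accuracy(phases, truth)
        ms = {}
        if mel1:
            ms["melanoma"] = m1[mel1]
        if mono1:
            ms["monocyte"] = m1[mono1]
        corr_table = cdc.correlate_to_markers(m1, markers, min_obs=cfg.min_obs,
                                              fdr=cfg.marker_fdr)
        set_table = cdc.set_covariation_anova(ms, markers, gene_sets,
                                              min_set=cfg.min_set,
                                              min_obs=cfg.min_obs)
        _, _, split_rho = cdc.split_half_reproducibility(
            ms, markers, gene_sets, seed=cfg.seed, min_set=cfg.min_set,
            min_obs=cfg.min_obs)
        report.stages["cdc"] = {
            "n_bulk_significant": int((anova["q"] < cfg.bulk_fdr).sum()),
            "markers": {ph: list(v) for ph, v in markers.proteins.items()},
            "pattern_rho": float(pattern.rho) if pattern else np.nan,
            "pattern_p": float(pattern.p) if pattern else np.nan,
            "n_marker_correlated": int(corr_table["significant"].sum()),
            "n_significant_sets": int((set_table["q"] < cfg.marker_fdr).sum())
            if len(set_table) else 0,
            "split_half_rho": split_rho,
        }
        report.metrics["phase_assignment_accuracy"] = acc
        report.metrics["marker_crossval_rho"] = float(pattern.rho) if pattern else np.nan
        report.metrics["split_half_rho"] = split_rho
        report.artifacts.update({"markers": markers, "phases": phases,
                                 "anova": anova, "corr_table": corr_table,
                                 "set_table": set_table, "pattern": pattern})

    # ----------------------------------------------------------- integrate
    integrated = None
    clusters_int = None
    if "integrate" in stages and len(m2) and mel1:
        mel2 = [c for c in m2.columns if ctype.get(c) == "melanoma"]
        im = align_datasets([m1[mel1], m2[mel2]], ["batch1", "batch2"])
        integrated = batch_correct(im)
        mi = quant.filter_min_observations(
            integrated.matrix, max(20, int(0.3 * integrated.matrix.shape[1])))
        mi_imp = knn_impute(mi, k=cfg.knn_k)
        pca_int = weighted_pca(mi_imp, n_components=2)
        clusters_int = cluster_two(pca_int.scores, random_state=cfg.seed)
        report.stages["integrate"] = {
            "n_shared_proteins": integrated.provenance.get("n_shared_proteins"),
            "n_cells": int(integrated.matrix.shape[1]),
            "cluster_sizes": {k: int(v) for k, v in
                              clusters_int.labels.value_counts().items()},
        }
        report.metrics["clusterB_recall_integrated"] = \
            _recall_b(clusters_int.labels, truth)
        report.artifacts.update({"integrated": integrated,
                                 "clusters_int": clusters_int})

    # -------------------------------------------------------------- subpop
    if "subpop" in stages and clusters1 is not None:
        m_mel = m1[mel1]
        ps = subpop_mod.psea(m_mel, clusters1, gene_sets, min_set=cfg.min_set,
                             completeness=cfg.psea_completeness,
                             fdr=cfg.psea_fdr, min_effect=cfg.psea_min_effect)
        use_m = integrated.matrix if integrated is not None else m_mel
        use_cl = clusters_int if clusters_int is not None else clusters1
        dk = subpop_mod.diff_kw(use_m, use_cl, min_frac_obs=cfg.kw_min_frac_obs,
                                fdr=cfg.kw_fdr, min_log2fc=cfg.min_log2fc)
        sig = dk.index[dk["significant"]] if len(dk) else pd.Index([])
        comp = None
        if phases is not None:
            comp = subpop_mod.phase_by_cluster(phases, clusters1)
        conc = subpop_mod.concentration_analysis(pep, sim.cell_meta, clusters1)
        grad = None
        if len(sig) >= 10:
            up_a = dk.loc[sig][dk.loc[sig, "effect"] < 0].index
            up_b = dk.loc[sig][dk.loc[sig, "effect"] > 0].index
            grad = subpop_mod.gradient_pca(use_m, list(sig), list(up_a), list(up_b))
        report.stages["subpop"] = {
            "n_enriched_sets": int(ps["significant"].sum()) if len(ps) else 0,
            "n_diff_proteins": int(len(sig)),
            "concentration_ratio_BA": conc["concentration_ratio_BA"],
            "concentration_p": conc["p"],
            "phase_fractions_by_cluster": comp["fractions"].to_dict()
            if comp else None,
            "gradient_spearman_A": grad["spearman_pc1_A"] if grad else np.nan,
        }
        report.artifacts.update({"psea": ps, "diff": dk, "concentration": conc,
                                 "gradient": grad, "phase_by_cluster": comp})


def _aux_ids(meta: pd.DataFrame) -> set:
    aux = meta["is_carrier"] | meta["is_reference"]
    return set(meta.loc[aux, "cell_id"])


def _phase_accuracy(phases: pd.Series, truth: pd.DataFrame) -> float:
    common = phases.index.intersection(truth.index)
    ph = phases[common]
    ok = ph != "NA"
    if ok.sum() == 0:
        return float("nan")
    return float((ph[ok] == truth.loc[common, "phase"][ok]).mean())


def _recall_b(labels: pd.Series, truth: pd.DataFrame) -> float:
    common = labels.index.intersection(truth.index)
    true_b = truth.loc[common, "cluster"] == "B"
    if true_b.sum() == 0:
        return float("nan")
    return float((labels[common][true_b] == "B").mean())
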