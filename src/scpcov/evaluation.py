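"""Self-contained evaluation runs used for acceptance-style reporting.

Each function regenerates its inputs from the synthetic-data generator at
the study's default conditions, executes the relevant analysis through
the public package surface, and measures the result against the known
ground truth.  All randomness derives from the single seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cdc, quant, subpop as subpop_mod
from .cluster import cluster_two
from .config import PipelineConfig, SimConfig
from .integrate import IntegratedMatrix, batch_correct
from .pca import weighted_pca
from .pipeline import RunReport, run_pipeline
from .sim import make_gene_sets, simulate_dataset

__all__ = ["default_report", "quota_exactness", "batch_shift_residual",
           "fdr_null_rates", "diff_recovery"]


def _child(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2 ** 31)


def default_report(seed: int) -> RunReport:
    """Full pipeline on the default study conditions (~1200 single cells,
    1200 proteins, two batches)."""
    cfg = PipelineConfig()
    cfg.seed = seed
    cfg.sim.seed = seed
    return run_pipeline(cfg)


def quota_exactness(seed: int, n_cells: int = 1000) -> dict:
    """Greedy assignment on arbitrary marker values: the realized phase
    counts must equal the quota bins exactly (up to flooring)."""
    rng = np.random.default_rng(_child(seed, 1))
    values = pd.DataFrame(rng.normal(size=(n_cells, 3)),
                          columns=["G1", "S", "G2"],
                          index=[f"c{i:04d}" for i in range(n_cells)])
    quotas = {"G1": 0.50, "S": 0.25, "G2": 0.25}
    got = cdc.greedy_assign(values, quotas)
    counts = got.value_counts()
    exp_s = int(np.floor(n_cells * 0.25))
    dev = max(abs(int(counts.get("S", 0)) - exp_s),
              abs(int(counts.get("G2", 0)) - exp_s),
              abs(int(counts.get("G1", 0)) - (n_cells - 2 * exp_s)))
    return {"max_count_deviation": dev, "n": n_cells}


def batch_shift_residual(seed: int, shift: float = 1.0) -> dict:
    """Residual per-protein batch-mean difference after correcting a
    planted uniform +1 shift."""
    rng = np.random.default_rng(_child(seed, 2))
    a = pd.DataFrame(rng.normal(size=(60, 50)),
                     index=[f"P{i}" for i in range(60)],
                     columns=[f"a{j}" for j in range(50)])
    b = pd.DataFrame(rng.normal(size=(60, 50)) + shift,
                     index=a.index, columns=[f"b{j}" for j in range(50)])
    a[rng.random(a.shape) < 0.2] = np.nan
    b[rng.random(b.shape) < 0.2] = np.nan
    raw = pd.concat([a, b], axis=1)
    im = IntegratedMatrix(matrix=raw, batches=pd.Series(
        ["b1"] * 50 + ["b2"] * 50, index=raw.columns))
    out = batch_correct(im)
    m1 = out.matrix[[c for c in out.matrix.columns if c.startswith("a")]] \
        .mean(axis=1, skipna=True)
    m2 = out.matrix[[c for c in out.matrix.columns if c.startswith("b")]] \
        .mean(axis=1, skipna=True)
    return {"max_batch_mean_diff": float((m1 - m2).abs().max()),
            "n": int(out.matrix.shape[0])}


def _null_sim_config(seed: int) -> SimConfig:
    return SimConfig(
        n_cells_per_type={"melanoma": 150, "monocyte": 150},
        n_negative_controls=0, n_proteins=400, seed=seed)


def fdr_null_rates(seed: int, n_seeds: int = 20, marker_fdr: float = 0.05,
                   psea_fdr: float = 0.01) -> dict:
    """Realized flag rates on global-null features, aggregated over
    ``n_seeds`` replicate simulations.

    Marker-correlation screen: tested proteins carry no periodic or
    cluster effect (the markers themselves come from the planted periodic
    proteins of the same dataset), so every flag is false.  Enrichment
    screen: cluster labels are randomly permuted, so every flagged set is
    false."""
    marker_flags = marker_tests = 0
    psea_flags = psea_tests = 0
    for k in range(n_seeds):
        cfg = _null_sim_config(_child(seed, 10 + k))
        sim = simulate_dataset(cfg)
        truth = sim.truth.set_index("cell_id")
        pt = sim.protein_truth.set_index("protein_id")
        m = quant.normalize_scope2(sim.peptide_table, sim.cell_meta)
        rng = np.random.default_rng(_child(seed, 500 + k))

        mono = m[[c for c in m.columns
                  if truth.loc[c, "cell_type"] == "monocyte"]]
        candidates = {ph: [p for p in pt.index[pt["periodic_phase"] == ph]
                           if p in mono.index][:8]
                      for ph in ("G1", "S", "G2")}
        markers = cdc.construct_phase_markers(mono, candidates)
        null_prots = [p for p in mono.index
                      if pt.loc[p, "periodic_phase"] == "NA"
                      and pt.loc[p, "diff_sign"] == "NA"]
        tab = cdc.correlate_to_markers(mono.loc[null_prots], markers,
                                       min_obs=int(0.125 * mono.shape[1]),
                                       fdr=marker_fdr, vectors_from=mono)
        marker_flags += int(tab["significant"].sum())
        marker_tests += int(tab["p"].notna().sum())

        mel = m[[c for c in m.columns
                 if truth.loc[c, "cell_type"] == "melanoma"]]
        labels = truth.loc[mel.columns, "cluster"].to_numpy(object)
        perm = pd.Series(rng.permutation(labels), index=mel.columns)
        # draw set members from well-observed proteins so the sets actually
        # clear the completeness floor and the test runs
        pool = mel.index[mel.notna().mean(axis=1) >= 0.9].to_numpy()
        sets = {f"null{j}": list(rng.choice(pool, 10, replace=False))
                for j in range(40)}
        ps = subpop_mod.psea(mel, perm, sets, fdr=psea_fdr)
        if len(ps):
            psea_flags += int(ps["significant"].sum())
            psea_tests += int(len(ps))
    return {
        "marker_null_flag_rate": marker_flags / max(marker_tests, 1),
        "marker_tests": marker_tests,
        "psea_null_flag_rate": psea_flags / max(psea_tests, 1),
        "psea_tests": psea_tests,
    }


def diff_recovery(seed: int) -> dict:
    """Recovery of the planted cluster-differential proteins.

    600 melanoma cells (cluster B fraction 0.2, ~480/120), 75 planted
    proteins at 2-fold or more, no gradient; Kruskal-Wallis at FDR 1%
    plus the 2-fold decision rule, against the generator's truth."""
    cfg = SimConfig(n_cells_per_type={"melanoma": 600},
                    n_negative_controls=20, gradient=False, n_batches=1,
                    seed=_child(seed, 3))
    sim = simulate_dataset(cfg)
    m = quant.normalize_scope2(sim.peptide_table, sim.cell_meta)
    truth = sim.truth.set_index("cell_id")
    clusters = truth.loc[[c for c in m.columns], "cluster"]
    tab = subpop_mod.diff_kw(m, clusters, fdr=0.01, min_log2fc=1.0)
    pt = sim.protein_truth.set_index("protein_id")
    planted = set(pt.index[pt["diff_sign"] != "NA"])
    sig = set(tab.index[tab["significant"]])
    recall = len(sig & planted) / len(planted)
    fdr = len(sig - planted) / max(len(sig), 1)
    return {"recall": recall, "empirical_fdr": fdr,
            "n_planted": len(planted), "n_flagged": len(sig),
            "n_cells": int(m.shape[1])}
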