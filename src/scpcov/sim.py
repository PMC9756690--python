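"""Synthetic single-cell proteomics data with ground truth.

The generator produces the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be tested against a known
truth table without any external download:

* log2-scale protein baselines spanning several orders of magnitude, with
  1-8 peptides per protein and missed-cleavage variant peptides;
* total signal per cell scaling with cell volume (diameter cubed) times a
  per-cell delivery/concentration factor;
* cell-division-cycle periodic proteins whose expected level peaks in
  their designated phase (peak - trough = ``periodic_amplitude``);
* two melanoma subpopulations: a majority cluster A and a primed cluster B
  carrying >= 2-fold differential proteins, a lower protein concentration
  per unit volume, a G1-shifted phase distribution, and (optionally) a
  within-A gradient that scales the differential effects continuously;
* carrier (100-cell) and reference (5-cell) channels per isobaric set,
  plus negative-control droplets ~20-fold dimmer than single cells;
* missingness applied per measurement through a logistic
  missing-not-at-random model on latent log2 intensity, plus a uniform
  missing-completely-at-random component;
* two acquisition batches with per-protein location/scale distortions and
  different multiplexing designs (14-cell isobaric sets with carrier and
  reference versus 3-cell sets with restricted protein coverage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "SimOutput",
    "simulate_dataset",
    "simulate_bulk_sorted",
    "make_gene_sets",
    "write_sim",
]

PHASES = ("G1", "S", "G2")


@dataclass
class SimOutput:
    """Everything the generator knows about one simulated experiment."""

    peptide_table: pd.DataFrame      # long-format observed quantifications
    protein_expected: pd.DataFrame   # proteins x single cells, log2 effects
    protein_observed: pd.DataFrame   # expected with NaN where undetected
    cell_meta: pd.DataFrame          # per-channel metadata (incl. controls)
    truth: pd.DataFrame              # per-single-cell ground truth
    protein_truth: pd.DataFrame      # per-protein ground truth
    config: SimConfig

    @property
    def single_cells(self) -> pd.Index:
        m = self.cell_meta
        keep = ~(m["is_negative_control"] | m["is_carrier"] | m["is_reference"])
        return pd.Index(m.loc[keep, "cell_id"])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sample_phases(rng, n, fractions: dict) -> np.ndarray:
    probs = np.array([fractions.get(p, 0.0) for p in PHASES])
    return rng.choice(np.array(PHASES, dtype=object), size=n, p=probs / probs.sum())


class _Landscape:
    """Protein/peptide layout drawn deterministically from ``cfg.seed``.

    Both the single-cell and the pseudo-bulk generator consume this first,
    from the same stream, so their protein-level ground truth agrees.
    """

    def __init__(self, cfg: SimConfig):
        rng = np.random.default_rng(cfg.seed)
        n_prot = cfg.n_proteins
        self.prot_ids = np.array([f"P{i:04d}" for i in range(n_prot)])
        self.base = rng.normal(cfg.base_mean, cfg.base_sd, n_prot)
        lo, hi = cfg.peptides_per_protein
        self.npep = rng.integers(lo, hi + 1, n_prot)

        # planted structure lives in the measurable (upper-abundance)
        # stratum: ground-truth recovery is only meaningful for proteins
        # the instrument can actually quantify
        eligible = np.where(self.base >= np.median(self.base))[0]
        n_periodic_total = 3 * cfg.n_periodic_proteins
        n_planted = n_periodic_total + cfg.n_diff_proteins
        if n_planted > eligible.size:
            raise ConfigError("not enough proteins for the requested planted structure")
        planted = rng.choice(eligible, size=n_planted, replace=False)
        self.periodic_idx = planted[:n_periodic_total]
        self.diff_idx = planted[n_periodic_total:]

        self.periodic_phase = np.full(n_prot, "", dtype=object)
        for k, ph in enumerate(PHASES):
            sel = self.periodic_idx[k * cfg.n_periodic_proteins:
                                    (k + 1) * cfg.n_periodic_proteins]
            self.periodic_phase[sel] = ph

        self.diff_sign = np.zeros(n_prot)
        half = cfg.n_diff_proteins // 2
        self.diff_sign[self.diff_idx[:half]] = -1.0   # up in cluster A
        self.diff_sign[self.diff_idx[half:]] = +1.0   # up in cluster B
        self.diff_mag = np.zeros(n_prot)
        self.diff_mag[self.diff_idx] = rng.uniform(
            cfg.diff_log2fc, 2 * cfg.diff_log2fc, cfg.n_diff_proteins)

        # cell-type proteome divergence: mean-zero log2 offsets applied to
        # melanoma cells for a random subset of unplanted proteins (kept off
        # the planted proteins so the planted effect sizes stay exact)
        self.type_eff = np.zeros(n_prot)
        unplanted = np.setdiff1d(np.arange(n_prot), planted)
        n_type = min(cfg.n_type_diff_proteins, unplanted.size)
        if n_type and cfg.type_log2fc_sd > 0:
            sel = rng.choice(unplanted, size=n_type, replace=False)
            self.type_eff[sel] = rng.normal(0.0, cfg.type_log2fc_sd, n_type)

        # batch-2 acquisition covers a protein subset (always incl. diff)
        n_cov = max(int(round(cfg.batch2_protein_fraction * n_prot)),
                    self.diff_idx.size)
        self.covered2 = np.zeros(n_prot, bool)
        self.covered2[self.diff_idx] = True
        pool = np.setdiff1d(np.arange(n_prot), self.diff_idx)
        n_extra = min(max(n_cov - self.diff_idx.size, 0), pool.size)
        self.covered2[rng.choice(pool, size=n_extra, replace=False)] = True

        # peptides; missed-cleavage variants are extra rows next to parents
        pep_prot, pep_off, pep_id, pep_mc = [], [], [], []
        for i in range(n_prot):
            offs = rng.normal(0.0, cfg.pep_offset_sd, self.npep[i])
            has_mc = rng.random(self.npep[i]) < cfg.missed_cleavage_fraction
            for j in range(self.npep[i]):
                pep_prot.append(i)
                pep_off.append(offs[j])
                pep_id.append(f"{self.prot_ids[i]}_p{j}")
                pep_mc.append(0)
                if has_mc[j]:
                    pep_prot.append(i)
                    pep_off.append(offs[j] + math.log2(cfg.missed_cleavage_ratio))
                    pep_id.append(f"{self.prot_ids[i]}_p{j}mc")
                    pep_mc.append(1)
        self.pep_prot = np.array(pep_prot)
        self.pep_off = np.array(pep_off)
        self.pep_id = np.array(pep_id, dtype=object)
        self.pep_mc = np.array(pep_mc)
        self.row_base = self.base[self.pep_prot] + self.pep_off
        self.rng = rng  # continued by simulate_dataset

    def phase_effect(self, phase_labels: np.ndarray, amplitude: float) -> np.ndarray:
        """Protein x cell matrix of periodic effects for given cell phases."""
        eff = np.zeros((self.prot_ids.size, phase_labels.size))
        for ph in PHASES:
            rows = np.where(self.periodic_phase == ph)[0]
            if rows.size:
                ind = (phase_labels == ph).astype(float) - 1.0 / 3.0
                eff[rows] += amplitude * ind[None, :]
        return eff


def simulate_dataset(config: Optional[SimConfig] = None) -> SimOutput:
    """Generate one synthetic experiment; deterministic given ``config.seed``."""
    cfg = config if config is not None else SimConfig()
    cfg.validate()
    land = _Landscape(cfg)
    rng = land.rng
    n_prot = cfg.n_proteins
    prot_ids, pep_prot, pep_mc = land.prot_ids, land.pep_prot, land.pep_mc
    row_base = land.row_base
    n_pep = pep_prot.size

    # ---------------- cells ----------------
    if cfg.n_cells_per_type:
        types, counts = zip(*cfg.n_cells_per_type.items())
        cell_type = np.array(sum(([t] * c for t, c in zip(types, counts)), []),
                             dtype=object)
    else:
        cell_type = np.array([], dtype=object)
    n_sc = cell_type.size
    cell_id = np.array([f"{t[:3]}{i:04d}" for i, t in enumerate(cell_type)],
                       dtype=object)

    is_mel = cell_type == "melanoma"
    cluster = np.full(n_sc, "NA", dtype=object)
    if is_mel.any():
        b = rng.random(n_sc) < cfg.subpop_fraction_b
        cluster[is_mel & b] = "B"
        cluster[is_mel & ~b] = "A"

    phase = np.empty(n_sc, dtype=object)
    for t in dict.fromkeys(cell_type):
        m = cell_type == t
        phase[m] = _sample_phases(rng, m.sum(), cfg.phase_fractions)
    if cfg.phase_fractions_b is not None and (cluster == "B").any():
        mb = cluster == "B"
        phase[mb] = _sample_phases(rng, mb.sum(), cfg.phase_fractions_b)

    diameter = np.full(n_sc, np.nan)
    for t, (mu, sd) in cfg.diameter_lognormal_params.items():
        m = cell_type == t
        diameter[m] = np.exp(rng.normal(mu, sd, m.sum()))

    grad = np.full(n_sc, np.nan)
    state = np.zeros(n_sc)
    state[cluster == "B"] = 1.0
    if cfg.gradient:
        ma = cluster == "A"
        grad[ma] = rng.uniform(0.0, 1.0, ma.sum())
        state[ma] = cfg.gradient_strength * grad[ma]

    conc = np.where(cluster == "B", cfg.concentration_offset_b, 1.0)
    cell_lognoise = rng.normal(0.0, cfg.cell_noise_sd, n_sc)
    size_factor = (diameter / cfg.reference_diameter) ** 3 * conc * 2.0 ** cell_lognoise

    batch = np.full(n_sc, "batch1", dtype=object)
    if cfg.n_batches == 2 and is_mel.any():
        b2 = is_mel & (rng.random(n_sc) < cfg.melanoma_batch2_fraction)
        batch[b2] = "batch2"

    n_neg = cfg.n_negative_controls
    neg_id = np.array([f"neg{i:04d}" for i in range(n_neg)], dtype=object)

    # ---------------- sets and channels ----------------
    set_of: dict = {}
    channel_of: dict = {}
    b1_pool = list(cell_id[batch == "batch1"]) + list(neg_id)
    rng.shuffle(b1_pool)
    k1 = cfg.cells_per_set.get("batch1", 14)
    b1_sets = []
    for s, start in enumerate(range(0, len(b1_pool), k1)):
        sid = f"s{s:03d}"
        b1_sets.append(sid)
        for ch, cid in enumerate(b1_pool[start:start + k1]):
            set_of[cid] = sid
            channel_of[cid] = f"RI{ch + 1}"
    b2_pool = list(cell_id[batch == "batch2"])
    rng.shuffle(b2_pool)
    k2 = cfg.cells_per_set.get("batch2", 3)
    for s, start in enumerate(range(0, len(b2_pool), k2)):
        sid = f"d{s:03d}"
        for ch, cid in enumerate(b2_pool[start:start + k2]):
            set_of[cid] = sid
            channel_of[cid] = f"mT{ch}"

    n_set1 = len(b1_sets)
    car_id = np.array([f"{s}_carrier" for s in b1_sets], dtype=object)
    ref_id = np.array([f"{s}_reference" for s in b1_sets], dtype=object)

    # ---------------- latent log2 intensities ----------------
    eff = land.phase_effect(phase, cfg.periodic_amplitude)
    di = land.diff_idx
    if di.size:
        eff[di] += (land.diff_sign[di] * land.diff_mag[di])[:, None] * state[None, :]
    if is_mel.any():
        eff += land.type_eff[:, None] * is_mel[None, :].astype(float)

    col_term = np.log2(size_factor) + math.log2(cfg.delivery_efficiency)
    dev = col_term[None, :] + eff[pep_prot, :] \
        + rng.normal(0.0, cfg.noise_sd, (n_pep, n_sc))

    if cfg.n_batches == 2:
        shift2 = rng.normal(0.0, cfg.batch_shift_sd, n_prot)
        scale2 = np.exp(rng.normal(0.0, cfg.batch_scale_sd, n_prot))
    else:
        shift2 = np.zeros(n_prot)
        scale2 = np.ones(n_prot)
    L_sc = row_base[:, None] + dev
    b2cols = batch == "batch2"
    if b2cols.any():
        L_sc[:, b2cols] = (row_base[:, None] + shift2[pep_prot, None]
                           + scale2[pep_prot, None] * dev[:, b2cols])

    # negative controls: background drawn so that the expected linear-scale
    # total is 1/background_ratio of the mean single-cell total
    mean_factor = float(np.mean(2.0 ** col_term)) if n_sc else 1.0
    neg_mu = (math.log2(mean_factor) - math.log2(cfg.background_ratio)
              - cfg.background_noise_sd ** 2 * math.log(2) / 2.0)
    L_neg = (row_base[:, None] + neg_mu
             + rng.normal(0.0, cfg.background_noise_sd, (n_pep, n_neg)))

    # carrier / reference: bulk-prepared pools, no single-cell delivery loss
    b1sc = batch == "batch1"
    mean_size_b1 = float(np.mean(size_factor[b1sc])) if b1sc.any() else 1.0
    L_car = (row_base[:, None] + math.log2(max(cfg.carrier_cells, 1) * mean_size_b1)
             + rng.normal(0.0, 0.05, (n_pep, n_set1)))
    L_ref = (row_base[:, None] + math.log2(max(cfg.reference_cells, 1) * mean_size_b1)
             + rng.normal(0.0, 0.05, (n_pep, n_set1)))

    L = np.concatenate([L_sc, L_neg, L_car, L_ref], axis=1)
    col_ids = np.concatenate([cell_id, neg_id, car_id, ref_id])
    col_batch = np.concatenate([batch,
                                np.array(["batch1"] * (n_neg + 2 * n_set1), object)])
    col_is_neg = np.concatenate([np.zeros(n_sc, bool), np.ones(n_neg, bool),
                                 np.zeros(2 * n_set1, bool)])
    col_is_car = np.concatenate([np.zeros(n_sc + n_neg, bool),
                                 np.ones(n_set1, bool), np.zeros(n_set1, bool)])
    col_is_ref = np.concatenate([np.zeros(n_sc + n_neg + n_set1, bool),
                                 np.ones(n_set1, bool)])
    col_set = np.array(
        [set_of.get(c, c.split("_")[0] if "_" in str(c) else "NA") for c in col_ids],
        dtype=object)
    col_channel = np.array(
        [channel_of.get(c, "carrier" if car else ("reference" if ref else "NA"))
         for c, car, ref in zip(col_ids, col_is_car, col_is_ref)], dtype=object)

    # ---------------- missingness ----------------
    p_det = _sigmoid(cfg.mnar_a + cfg.mnar_b * L)
    keep = rng.random(L.shape) < p_det
    if cfg.mcar_rate > 0:
        keep &= rng.random(L.shape) >= cfg.mcar_rate
    if b2cols.any():
        uncovered = ~land.covered2[pep_prot]
        b2all = np.isin(col_ids, cell_id[b2cols])
        keep[np.ix_(uncovered, b2all)] = False

    # ---------------- long table ----------------
    r, c = np.where(keep)
    peptide_table = pd.DataFrame({
        "peptide_id": pd.Categorical.from_codes(r, categories=list(land.pep_id)),
        "protein_id": pd.Categorical.from_codes(pep_prot[r], categories=list(prot_ids)),
        "cell_id": pd.Categorical.from_codes(c, categories=list(col_ids)),
        "set_id": pd.Categorical(col_set[c]),
        "raw_intensity": 2.0 ** L[r, c],
        "n_missed_cleavages": pep_mc[r],
    })

    # ---------------- protein-level truth matrices ----------------
    sc_keep = keep[:, :n_sc].astype(np.int32)
    bounds = np.searchsorted(pep_prot, np.arange(n_prot))
    prot_seen = np.add.reduceat(sc_keep, bounds, axis=0) > 0 if n_pep else \
        np.zeros((n_prot, n_sc), bool)
    protein_expected = pd.DataFrame(eff, index=prot_ids, columns=cell_id)
    protein_observed = protein_expected.where(
        pd.DataFrame(prot_seen, index=prot_ids, columns=cell_id))

    # ---------------- metadata and truth ----------------
    dia = np.concatenate([diameter, np.full(n_neg + 2 * n_set1, np.nan)])
    ctype = np.concatenate([cell_type,
                            np.array(["NA"] * (n_neg + 2 * n_set1), dtype=object)])
    cell_meta = pd.DataFrame({
        "cell_id": col_ids, "cell_type": ctype, "set_id": col_set,
        "channel": col_channel, "diameter": dia,
        "is_negative_control": col_is_neg, "is_carrier": col_is_car,
        "is_reference": col_is_ref, "batch": col_batch,
        "cluster": "NA", "phase": "NA",
    })
    truth = pd.DataFrame({
        "cell_id": cell_id, "cell_type": cell_type, "phase": phase,
        "cluster": cluster, "gradient_position": grad, "diameter": diameter,
        "size_factor": size_factor, "batch": batch,
    })
    protein_truth = pd.DataFrame({
        "protein_id": prot_ids, "base_log2": land.base, "n_peptides": land.npep,
        "periodic_phase": np.where(land.periodic_phase == "", "NA",
                                   land.periodic_phase),
        "diff_sign": np.where(land.diff_sign == 0, "NA",
                              np.where(land.diff_sign < 0, "up_A", "up_B")),
        "diff_log2fc": land.diff_mag, "type_log2fc": land.type_eff,
        "covered_batch2": land.covered2,
    })
    return SimOutput(peptide_table, protein_expected, protein_observed,
                     cell_meta, truth, protein_truth, cfg)


def simulate_bulk_sorted(
    config: SimConfig,
    n_replicates: int = 3,
    cell_types: Optional[Sequence[str]] = None,
    bulk_noise_sd: float = 0.15,
    sample_cells: int = 200,
) -> pd.DataFrame:
    """Phase-pure pseudo-bulk peptide table emulating DNA-content sorting.

    One sample column per (cell type, phase, replicate); intensities are
    the per-phase expectation of each peptide plus a per-sample loading
    shift and measurement noise.  No missingness is applied: bulk
    acquisitions are essentially complete at this depth.  The protein
    landscape (which proteins are periodic, and in which phase) is shared
    with :func:`simulate_dataset` for the same config.
    """
    if n_replicates < 2:
        raise ConfigError("n_replicates must be >= 2 for downstream ANOVA")
    cfg = config
    land = _Landscape(cfg)
    rng = np.random.default_rng((cfg.seed + 104729) % (2 ** 31))
    if cell_types is None:
        cell_types = list(cfg.n_cells_per_type)

    frames = []
    n_pep = land.pep_prot.size
    for t in cell_types:
        for ph in PHASES:
            eff = land.phase_effect(np.array([ph], dtype=object),
                                    cfg.periodic_amplitude)[:, 0]
            if t == "melanoma":
                eff = eff + land.type_eff
            for rep in range(n_replicates):
                loading = rng.normal(0.0, 0.2)
                vals = (land.row_base + math.log2(sample_cells)
                        + eff[land.pep_prot] + loading
                        + rng.normal(0.0, bulk_noise_sd, n_pep))
                frames.append(pd.DataFrame({
                    "peptide_id": land.pep_id,
                    "protein_id": land.prot_ids[land.pep_prot],
                    "sample_id": f"{t}_{ph}_r{rep}",
                    "cell_type": t, "phase": ph,
                    "raw_intensity": 2.0 ** vals,
                }))
    return pd.concat(frames, ignore_index=True)


def make_gene_sets(
    protein_truth: pd.DataFrame,
    n_null_sets: int = 20,
    set_size: int = 12,
    seed: int = 0,
    include_planted: bool = True,
) -> dict:
    """Gene-set collection over the simulated proteome.

    Planted sets collect the truly periodic proteins per phase and the
    cluster-differential proteins per direction; null sets are random
    draws from the unplanted proteins.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, list] = {}
    pt = protein_truth
    if include_planted:
        for ph in PHASES:
            ids = pt.loc[pt["periodic_phase"] == ph, "protein_id"].tolist()
            if ids:
                sets[f"{ph}_periodic"] = ids
        for tag, name in (("up_A", "clusterA_up"), ("up_B", "clusterB_up")):
            ids = pt.loc[pt["diff_sign"] == tag, "protein_id"].tolist()
            if ids:
                sets[name] = ids
    null_pool = pt.loc[(pt["periodic_phase"] == "NA") & (pt["diff_sign"] == "NA"),
                       "protein_id"].to_numpy()
    for k in range(n_null_sets):
        take = rng.choice(null_pool, size=min(set_size, null_pool.size),
                          replace=False)
        sets[f"null_{k:03d}"] = list(take)
    return sets


def write_sim(out: SimOutput, directory) -> dict:
    """Write every SimOutput component as TSV; returns {name: path}."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, idx in [
        ("peptide_table", out.peptide_table, False),
        ("protein_expected", out.protein_expected, True),
        ("protein_observed", out.protein_observed, True),
        ("cell_meta", out.cell_meta, False),
        ("truth", out.truth, False),
        ("protein_truth", out.protein_truth, False),
    ]:
        p = d / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=idx, na_rep="NA")
        paths[name] = str(p)
    return paths
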