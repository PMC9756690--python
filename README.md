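# scpcov

Protein covariation analysis for single-cell proteomics.

Single-cell mass-spectrometry experiments quantify hundreds to thousands
of proteins across thousands of individual cells. Beyond separating cell
*types*, the covariation of proteins **within** a cell type carries
biological signal: cell-division-cycle (CDC) dynamics, subpopulation
structure such as drug-resistance priming in melanoma, and continuous
transition states. Extracting it requires careful handling of
reporter-ion quantification, intensity-dependent (missing-not-at-random)
missingness, and batch structure. `scpcov` implements that workflow for
computational proteomics researchers, end to end, together with a
synthetic-data generator that reproduces the statistical structure of
such experiments with known ground truth, so every stage is testable
without any raw-data download.

## What it computes

- **Normalization (SCoPE2 convention).** Reporter-ion intensities RI are
  expressed relative to the per-set 5-cell reference channel, each cell
  column divided by its median, each peptide row by its mean, log2
  transformed, collapsed to proteins by the median peptide, and
  re-centered. Cells are quality-filtered on the median coefficient of
  variation (CV = σ/μ) of proteins quantified by > 5 peptides, threshold
  0.41.
- **Imputation and embedding.** k-nearest-neighbor imputation (k = 3,
  cell–cell Pearson similarity on pairwise-observed proteins) and two
  PCA flavors: *weighted PCA*, where protein *i* is weighted by
  wᵢ = Σⱼ r²ᵢⱼ over the protein–protein correlation matrix before the
  SVD, and *correlation PCA*, the top eigenvectors of the
  pairwise-complete cell × cell correlation matrix (no imputation).
- **CDC phase markers.** Proteins differential across FACS-sorted G1/S/G2
  pseudo-bulk samples (one-way ANOVA, Benjamini–Hochberg q-values) seed a
  combinatorial search: all 2–3 protein combinations are averaged per
  cell and, per phase, the two disjoint combinations with the highest
  mutual correlation — negative against the other phases' selections —
  form the marker. Markers trained on one cell type are cross-validated
  on the other via the correlation of their 6 × 6 marker-group
  correlation patterns.
- **Covariation screening.** Spearman correlation of every protein
  (≥ 150 observations) with each phase-marker vector, BH-corrected;
  gene-set level ANOVA over the 6 distributions of member correlations
  (two cell types × three phases, ≥ 4 proteins per set) with split-half
  reproducibility.
- **Phase assignment.** A greedy, quota-constrained rule: all
  (cell, phase) marker abundances sorted descending and assigned subject
  to bins of 50 % G1, 25 % S, 25 % G2.
- **Subpopulations.** Two-means clustering in PC space (cluster A = the
  larger cluster), protein-set enrichment (t-test on observed values,
  FDR < 1 %, effect > 50 %), per-protein Kruskal–Wallis differential
  testing with the 2-fold rule, phase composition per cluster, protein
  concentration (total signal over sphere volume (π/6)d³), within-cluster
  correlation structure, and a gradient embedding in the space of the
  differential proteins.
- **Integration.** Alignment of datasets from different MS methods on
  their shared proteins and deterministic per-protein location/scale
  batch correction on observed values.

## Worked example

```python
from scpcov import (SimConfig, simulate_dataset, simulate_bulk_sorted,
                    normalize_scope2, filter_cells_by_cv)
from scpcov.cdc import (bulk_phase_anova, select_candidates,
                        construct_phase_markers, crossvalidate_markers,
                        assign_phases_greedy)
from scpcov.quant import peptide_relative_matrix

cfg = SimConfig(n_cells_per_type={"melanoma": 300, "monocyte": 300},
                n_negative_controls=30, n_proteins=600, seed=7)
sim = simulate_dataset(cfg)

kept, cv, _ = filter_cells_by_cv(sim.peptide_table, sim.cell_meta)
print(f"cells passing CV filter: {len(kept)} (median CV {cv.median():.2f})")

m = normalize_scope2(sim.peptide_table, sim.cell_meta)
print(f"normalized matrix: {m.shape[0]} proteins x {m.shape[1]} cells")

bulk = simulate_bulk_sorted(cfg, n_replicates=3)
anova = bulk_phase_anova(bulk)
print(f"bulk phase ANOVA: {(anova['q'] < 0.01).sum()} proteins at q < 0.01")

pep_rel = peptide_relative_matrix(sim.peptide_table, sim.cell_meta)
prot_of = sim.peptide_table.drop_duplicates("peptide_id") \
    .set_index("peptide_id")["protein_id"].astype(str)
cands = select_candidates(anova, pep_rel, prot_of)
truth = sim.truth.set_index("cell_id")
mono = m[[c for c in m.columns if truth.loc[c, "cell_type"] == "monocyte"]]
mel = m[[c for c in m.columns if truth.loc[c, "cell_type"] == "melanoma"]]
markers = construct_phase_markers(mono, cands, training_cell_type="monocyte")
pattern = crossvalidate_markers(markers, mono, mel)
print(f"marker pattern cross-validation: rho = {pattern.rho:.2f}, "
      f"p = {pattern.p:.2g}")

phases = assign_phases_greedy(m, markers)
acc = (phases[phases != 'NA'] ==
       truth.loc[phases.index[phases != 'NA'], 'phase']).mean()
print(f"greedy phase assignment accuracy vs truth: {acc:.2f}")
```

Output:

```
cells passing CV filter: 601 (median CV 0.20)
normalized matrix: 600 proteins x 600 cells
bulk phase ANOVA: 60 proteins at q < 0.01
marker pattern cross-validation: rho = 0.99, p = 5.2e-14
greedy phase assignment accuracy vs truth: 0.99
```

601 of 630 prepared channels survive the CV filter (negative-control
droplets fail it); the 60 ANOVA hits are exactly the 3 × 20 planted
periodic proteins; markers built on monocytes alone reproduce their
within/cross-phase correlation pattern on the held-out melanoma cells
(ρ = 0.99); and the quota-constrained assignment recovers the true phase
of 99 % of cells at this noise level.

The same steps are available from the shell:

```bash
scpcov simulate --out data/ --seed 7
scpcov normalize data/peptide_table.tsv data/cell_meta.tsv --out norm.tsv
scpcov qc data/peptide_table.tsv data/cell_meta.tsv
scpcov run --out-dir results/ --seed 1     # full pipeline + JSON report
```

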