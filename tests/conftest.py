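"""Shared fixtures: small synthetic experiments reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scpcov import SimConfig, simulate_dataset
from scpcov.cdc import construct_phase_markers
from scpcov.quant import filter_min_observations, normalize_scope2


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_cells_per_type={"melanoma": 150, "monocyte": 150},
        n_negative_controls=15,
        n_proteins=300,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_matrices(small_sim):
    """Normalized batch-1 matrix plus per-cell-type views."""
    sim = small_sim
    truth = sim.truth.set_index("cell_id")
    meta = sim.cell_meta
    aux = set(meta.loc[meta["is_carrier"] | meta["is_reference"], "cell_id"])
    b1 = set(truth.index[truth["batch"] == "batch1"])
    pep = sim.peptide_table
    sub = pep[pep["cell_id"].astype(str).isin({str(c) for c in b1 | aux})].copy()
    for col in ("peptide_id", "protein_id", "cell_id", "set_id"):
        sub[col] = sub[col].astype(str)
    m1 = normalize_scope2(sub, meta)
    ctype = truth["cell_type"]
    by_type = {t: m1[[c for c in m1.columns if ctype.get(c) == t]]
               for t in ("melanoma", "monocyte")}
    return {"m1": m1, "by_type": by_type, "truth": truth}


@pytest.fixture(scope="session")
def small_markers(small_sim, small_matrices):
    """Markers constructed on monocytes from the planted periodic proteins."""
    pt = small_sim.protein_truth
    candidates = {ph: pt.loc[pt["periodic_phase"] == ph, "protein_id"].tolist()[:8]
                  for ph in ("G1", "S", "G2")}
    mono = small_matrices["by_type"]["monocyte"]
    return construct_phase_markers(mono, candidates, training_cell_type="monocyte")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_missing_matrix(rng, n_prot=10, n_cell=10, miss=0.2) -> pd.DataFrame:
    X = rng.normal(size=(n_prot, n_cell))
    mask = rng.random((n_prot, n_cell)) < miss
    X[mask] = np.nan
    return pd.DataFrame(X, index=[f"P{i}" for i in range(n_prot)],
                        columns=[f"c{j}" for j in range(n_cell)])
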