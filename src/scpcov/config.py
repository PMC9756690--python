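"""Configuration objects for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


def _default_cells() -> dict:
    return {"melanoma": 600, "monocyte": 600}


def _default_phases() -> dict:
    return {"G1": 0.50, "S": 0.25, "G2": 0.25}


def _default_phases_b() -> dict:
    # primed cells accumulate in G1
    return {"G1": 0.78, "S": 0.18, "G2": 0.04}


def _default_diameters() -> dict:
    # natural-log mean/sd of cell diameter in micrometers:
    # melanoma ~14 um, monocytes ~10 um
    return {"melanoma": (2.64, 0.12), "monocyte": (2.30, 0.12)}


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell proteomics generator.

    The defaults emulate the study conditions of a two-cell-type
    (melanoma + monocyte) experiment: ~1200 single cells plus negative
    controls, log-scale protein abundances spanning several orders of
    magnitude, cell-size scaling of total signal, cell-cycle-periodic
    proteins, a primed melanoma subpopulation (cluster B) with >= 2-fold
    differential proteins and a within-cluster-A gradient, intensity-
    dependent (MNAR) plus random (MCAR) missingness, and two acquisition
    batches with different multiplexing designs.
    """

    # populations
    n_cells_per_type: dict = field(default_factory=_default_cells)
    n_negative_controls: int = 60
    n_proteins: int = 1200
    peptides_per_protein: tuple = (1, 8)

    # cell cycle
    phase_fractions: dict = field(default_factory=_default_phases)
    phase_fractions_b: Optional[dict] = field(default_factory=_default_phases_b)
    n_periodic_proteins: int = 20          # per phase
    periodic_amplitude: float = 1.0        # log2 peak - trough

    # cell-type differences (proteome divergence between the two types)
    n_type_diff_proteins: int = 200
    type_log2fc_sd: float = 0.5

    # melanoma subpopulations
    subpop_fraction_b: float = 0.2
    n_diff_proteins: int = 75
    diff_log2fc: float = 1.0               # per-protein |FC| ~ U(fc, 2 fc)
    gradient: bool = True
    gradient_strength: float = 0.3
    concentration_offset_b: float = 0.8    # protein per unit volume in B

    # cell geometry / scaling
    diameter_lognormal_params: dict = field(default_factory=_default_diameters)
    reference_diameter: float = 12.0       # um, size-factor normalizer
    cell_noise_sd: float = 0.35            # per-cell log2 delivery/conc. noise

    # intensity model (log2 arbitrary units); calibrated so that the default
    # configuration yields ~60% protein-level completeness and a ~20-fold
    # negative-control intensity deficit under the default MNAR model
    base_mean: float = 11.0
    base_sd: float = 4.5
    pep_offset_sd: float = 2.0
    noise_sd: float = 0.3                  # log2 measurement noise

    # missingness
    mnar_a: float = -6.0
    mnar_b: float = 0.5
    mcar_rate: float = 0.05

    # controls and channels
    background_ratio: float = 20.0
    background_noise_sd: float = 1.0
    delivery_efficiency: float = 0.95
    carrier_cells: int = 100
    reference_cells: int = 5

    # peptide-level structure
    missed_cleavage_fraction: float = 0.10
    missed_cleavage_ratio: float = 0.07    # missed / fully-cleaved intensity

    # batches: batch1 = isobaric 14-cell sets with carrier/reference;
    # batch2 = 3-cell sets, no carrier, restricted protein coverage
    n_batches: int = 2
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    melanoma_batch2_fraction: float = 0.3
    batch2_protein_fraction: float = 0.35
    cells_per_set: dict = field(default_factory=lambda: {"batch1": 14, "batch2": 3})

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(self.phase_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(f"phase_fractions must sum to 1, got {total!r}")
        if self.phase_fractions_b is not None:
            tb = sum(self.phase_fractions_b.values())
            if abs(tb - 1.0) > 1e-12:
                raise ConfigError(f"phase_fractions_b must sum to 1, got {tb!r}")
        counts = [
            self.n_negative_controls, self.n_proteins,
            self.n_periodic_proteins, self.n_diff_proteins,
            *self.n_cells_per_type.values(),
        ]
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if not 0.0 <= self.subpop_fraction_b <= 1.0:
            raise ConfigError("subpop_fraction_b must lie in [0, 1]")
        if self.background_ratio <= 1.0:
            raise ConfigError("background_ratio must exceed 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein must be a range with min >= 1")
        if self.n_batches not in (1, 2):
            raise ConfigError("n_batches must be 1 or 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "peptides_per_protein" in d:
            d["peptides_per_protein"] = tuple(d["peptides_per_protein"])
        if "diameter_lognormal_params" in d:
            d["diameter_lognormal_params"] = {
                k: tuple(v) for k, v in d["diameter_lognormal_params"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineConfig:
    """End-to-end run configuration; every analysis constant is surfaced here."""

    sim: SimConfig = field(default_factory=SimConfig)

    # quant_io
    cv_threshold: float = 0.41
    cv_min_peptides: int = 6
    knn_k: int = 3
    min_obs: int = 150

    # cdc
    quotas: dict = field(default_factory=_default_phases)
    candidates_per_phase: int = 10
    marker_fdr: float = 0.05
    bulk_fdr: float = 0.01
    min_set: int = 4

    # subpop
    psea_fdr: float = 0.01
    psea_completeness: float = 0.8
    psea_min_effect: float = 0.5
    kw_fdr: float = 0.01
    kw_min_frac_obs: float = 0.5
    min_log2fc: float = 1.0

    # stage toggles
    stages: tuple = ("simulate", "normalize", "qc", "embed", "cdc", "subpop", "integrate")

    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(d.pop("sim", {}))
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=sim, **d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
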