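"""Readers and writers for the delimited-text formats used throughout.

All tabular data travel as TSV with the literal token ``NA`` for missing
values; gene sets use the GMT convention (set name, description, then
members, tab-separated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "SchemaError",
    "read_peptide_table",
    "read_cell_meta",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
]

REQUIRED_PEPTIDE_COLUMNS = ("peptide_id", "protein_id", "cell_id", "set_id",
                            "raw_intensity")


class SchemaError(ValueError):
    """A required column is absent from an input table."""


def read_peptide_table(
    path,
    schema: Optional[Mapping[str, str]] = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a long-format peptide/precursor quantification table.

    ``schema`` maps the standard column names to the names used in the
    file (identity by default), so MaxQuant-evidence- or DIA-NN-report-
    like exports can be ingested by renaming.  Nonpositive intensities
    are recorded as missing: a reporter-ion intensity of zero means the
    peptide was not detected in that channel, not that it is absent with
    perfect confidence.
    """
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in REQUIRED_PEPTIDE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "n_missed_cleavages" not in df.columns:
        df["n_missed_cleavages"] = 0
    df["raw_intensity"] = pd.to_numeric(df["raw_intensity"], errors="coerce")
    df.loc[df["raw_intensity"] <= 0, "raw_intensity"] = pd.NA
    df["raw_intensity"] = df["raw_intensity"].astype(float)
    dup = df.duplicated(subset=["peptide_id", "cell_id", "set_id"])
    if dup.any():
        bad = df.loc[dup, ["peptide_id", "cell_id", "set_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate (peptide, cell, set) rows, e.g. {bad}")
    return df


def read_cell_meta(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=["NA"],
                     keep_default_na=True)
    if "cell_id" not in df.columns:
        raise SchemaError(f"required column 'cell_id' missing from {path}")
    if df["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    for col in ("is_negative_control", "is_carrier", "is_reference"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Protein x cell matrix with NA for missing; first column is the index."""
    return pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])


def write_matrix(m: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.to_csv(path, sep=sep, na_rep="NA")


def read_gmt(path) -> dict:
    """GMT gene sets: one set per line — name, description, members."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_gmt(sets: Mapping[str, list], path, description: str = "synthetic") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")
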