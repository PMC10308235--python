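"""Tabular I/O: one TSV dialect (UTF-8, '.' decimal, 'NA' missing) with
schema-checked readers so every stage fails loudly on malformed input."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NA_MARKER = "NA"


class SchemaError(ValueError):
    """Input table header does not match the expected schema."""


@dataclass(frozen=True)
class TableSchema:
    """Required (and typed) columns for one kind of profile table.

    Extra columns are preserved untouched; missing required columns are
    fatal and reported by name.
    """

    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()

    def validate(self, df: pd.DataFrame, path: str | Path = "<table>") -> None:
        missing = [c for c in self.required if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: {self.name} table is missing required column(s) "
                + ", ".join(repr(c) for c in missing)
            )


GAS_SCHEMA = TableSchema(
    "gas", ("depth_mbsf", "h2_um", "ch4_mm"),
    ("depth_mbsf", "h2_um", "ch4_mm"),
)
KEELING_SCHEMA = TableSchema(
    "keeling", ("h2_ppmv", "dD_h2_permil"), ("h2_ppmv", "dD_h2_permil")
)
BATCH_SCHEMA = TableSchema(
    "fe_h2o_batches", ("T_C", "dD_h2o_permil", "dD_h2_permil"),
    ("T_C", "dD_h2o_permil", "dD_h2_permil"),
)
POREWATER_SCHEMA = TableSchema("porewater", ("depth_mbsf", "SO4"), ("depth_mbsf",))
SULFUR_SCHEMA = TableSchema(
    "sulfur", ("sample_id", "d33S_permil", "d34S_permil"),
    ("d33S_permil", "d34S_permil"),
)
DILUTION_SCHEMA = TableSchema("dilution", ("sample_id", "step", "positive"), ("step",))


def read_profile_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV into a typed table; 'NA' becomes missing.

    Numeric columns that fail to parse raise with the offending column and
    1-based data line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_MARKER, keep_default_na=False,
                     comment="#")
    schema.validate(df, path)
    for col in schema.numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            lines = (bad.isna() & df[col].notna())
            where = int(lines.idxmax()) + 2 if lines.any() else "?"
            raise SchemaError(
                f"{path}: column {col!r} is not numeric (first bad value on "
                f"line {where})"
            ) from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the single TSV dialect (UTF-8, '.', 'NA'); returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_MARKER)
    return path
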