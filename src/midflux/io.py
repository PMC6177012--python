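"""Validated readers and writers for the delimited-text interchange formats.

All files are UTF-8, comma-separated with "." decimals and LF endings;
missing values are empty fields.  Two sample-table dialects exist: wide
(one metabolite per column) and long (one row per sample x metabolite,
with ``mass_mg`` and ``is_intensity`` carried as reserved metabolite
names).  Isotopologue tables are long-format only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import META_COLUMNS, SampleTable

__all__ = [
    "read_sample_table",
    "write_sample_table",
    "read_mid_table",
    "write_mid_table",
    "read_pool_table",
    "write_pool_table",
]

#: reserved metabolite names that map to metadata columns in long dialect
RESERVED_LONG_NAMES = ("mass_mg", "is_intensity")

MID_COLUMNS = [
    "sample_id", "group", "metabolite", "fragment_formula",
    "tracer_element", "m_shift", "intensity",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    if missing := [c for c in required if c not in df.columns]:
        raise ValidationError(f"{path.name}: missing required column(s) {missing}")
    return df


def _check_numeric(df: pd.DataFrame, columns: list[str], path_name: str) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path_name}: non-numeric value in column {col!r} at row "
                f"{int(bad[0]) + 2} (counting the header as row 1)"
            )
        df[col] = coerced


def read_sample_table(path: str | Path, dialect: str = "wide") -> SampleTable:
    """Read a cohort table; metabolite names are whitespace-trimmed with
    case preserved, duplicate sample ids are rejected."""
    if dialect == "wide":
        df = _read_csv(path, ["sample_id", "group", "mass_mg", "is_intensity"])
        df.columns = [str(c).strip() for c in df.columns]
        metabolites = [c for c in df.columns if c not in ("sample_id", *META_COLUMNS)]
        _check_numeric(df, ["mass_mg", "is_intensity", *metabolites], Path(path).name)
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
            raise ValidationError(f"{Path(path).name}: duplicate sample_id(s) {dupes}")
        return SampleTable(data=df.set_index("sample_id"), normalized=False)
    if dialect == "long":
        df = _read_csv(path, ["sample_id", "group", "metabolite", "intensity"])
        df["metabolite"] = df["metabolite"].astype(str).str.strip()
        _check_numeric(df, ["intensity"], Path(path).name)
        df["sample_id"] = df["sample_id"].astype(str)
        if df.duplicated(["sample_id", "metabolite"]).any():
            raise ValidationError(
                f"{Path(path).name}: duplicate (sample_id, metabolite) rows"
            )
        wide = df.pivot(index="sample_id", columns="metabolite", values="intensity")
        groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
        for col in RESERVED_LONG_NAMES:
            if col not in wide.columns:
                raise ValidationError(
                    f"{Path(path).name}: long dialect requires rows for "
                    f"reserved metabolite {col!r}"
                )
        metabolites = [c for c in wide.columns if c not in RESERVED_LONG_NAMES]
        out = pd.concat(
            [groups, wide[list(RESERVED_LONG_NAMES)], wide[metabolites]], axis=1
        )
        out.columns.name = None
        return SampleTable(data=out, normalized=False)
    raise ValidationError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    df = table.data.reset_index()
    if "index" in df.columns:
        df = df.rename(columns={"index": "sample_id"})
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_mid_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format raw isotopologue table."""
    df = _read_csv(path, [c for c in MID_COLUMNS if c != "group"])
    if "group" not in df.columns:
        df["group"] = ""
    _check_numeric(df, ["m_shift", "intensity"], Path(path).name)
    if (df["intensity"] < 0).any():
        raise ValidationError(f"{Path(path).name}: negative isotopologue intensity")
    df["m_shift"] = df["m_shift"].astype(int)
    if df.duplicated(["sample_id", "metabolite", "m_shift"]).any():
        raise ValidationError(
            f"{Path(path).name}: duplicate (sample_id, metabolite, m_shift) rows"
        )
    return df[MID_COLUMNS]


def write_mid_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_pool_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["sample_id", "metabolite", "pool"])
    _check_numeric(df, ["pool"], Path(path).name)
    if (df["pool"] <= 0).any():
        raise ValidationError(f"{Path(path).name}: pools must be positive")
    return df


def write_pool_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
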