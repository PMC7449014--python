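"""CSV readers and writers with strict schema validation.

All dialects are UTF-8, comma-separated, '.' decimal, header required.
Floats are written with 9 significant digits so that re-running the
pipeline on identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "DIMENSION_COLUMNS",
    "ASSAY_COLUMNS",
    "GROWTH_COLUMNS",
    "SNAPSHOT_COLUMNS",
    "MER_COLUMNS",
    "read_table",
    "write_table",
    "read_dimensions",
    "read_assays",
    "read_growth",
]

FLOAT_FORMAT = "%.9g"

DIMENSION_COLUMNS: Dict[str, type] = {
    "sample_id": str,
    "day": float,
    "replicate": str,
    "image_id": str,
    "cell_id": str,
    "length_um": float,
    "width_um": float,
}

ASSAY_COLUMNS: Dict[str, type] = {
    "sample_id": str,
    "day": float,
    "replicate": str,
    "time_min": float,
    "absorbance": float,
    "cell_conc_per_ml": float,
    "extinction_mM_cm": float,
    "path_cm": float,
}

GROWTH_COLUMNS: Dict[str, type] = {
    "condition": str,
    "replicate": str,
    "day": float,
    "od750": float,
    "dilution_factor": float,
}

SNAPSHOT_COLUMNS = [
    "day", "condition", "mean_length_um", "sem_length", "mean_width_um",
    "mean_area_um2", "sem_area", "k_ms", "sem_k", "rate_mol_cell_s",
    "sem_rate", "delta_c_molm3", "sem_delta_c",
]

MER_COLUMNS = ["day", "dk", "dA", "dkA", "ddc", "dr", "mer", "dominance"]


def read_table(path: str | Path, schema: Dict[str, type]) -> pd.DataFrame:
    """Read a CSV and validate it against a column schema.

    Raises :class:`SchemaError` naming the offending column and (for
    value errors) the 1-based data line number.  Locale decimal commas in
    numeric columns fail float conversion and are rejected explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        raise SchemaError(f"{path.name}: unknown column(s) {unknown}")
    out = {}
    for col, kind in schema.items():
        raw = df[col]
        if kind is float:
            converted = pd.to_numeric(raw.str.strip(), errors="coerce")
            bad = converted.isna() & (raw.str.strip() != "")
            if bad.any():
                line = int(bad.idxmax()) + 2  # header is line 1
                value = raw[bad.idxmax()]
                hint = (
                    " (decimal commas are not accepted; use '.')"
                    if "," in value else ""
                )
                raise SchemaError(
                    f"{path.name}: column '{col}', line {line}: "
                    f"cannot parse {value!r} as a number{hint}"
                )
            if converted.isna().any():
                line = int(converted.isna().idxmax()) + 2
                raise SchemaError(
                    f"{path.name}: column '{col}', line {line}: empty value"
                )
            out[col] = converted.astype(float)
        else:
            out[col] = raw
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV with fixed 9-significant-digit float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _check_positive(df: pd.DataFrame, columns: Sequence[str], name: str):
    for col in columns:
        bad = df[col] <= 0
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{name}: column '{col}', line {line}: "
                f"non-positive value {df[col][bad.idxmax()]!r}"
            )


def read_dimensions(path: str | Path) -> pd.DataFrame:
    """Read the per-cell dimension table; enforces L >= D > 0."""
    df = read_table(path, DIMENSION_COLUMNS)
    _check_positive(df, ["length_um", "width_um"], Path(path).name)
    bad = df["length_um"] < df["width_um"]
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{Path(path).name}: line {line}: length_um < width_um "
            "violates the rod-shape invariant"
        )
    return df


def read_assays(path: str | Path) -> pd.DataFrame:
    """Read the assay table; enforces positive metadata and A >= 0."""
    df = read_table(path, ASSAY_COLUMNS)
    _check_positive(
        df, ["cell_conc_per_ml", "extinction_mM_cm", "path_cm"],
        Path(path).name,
    )
    if (df["absorbance"] < 0).any():
        bad = df["absorbance"] < 0
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{Path(path).name}: column 'absorbance', line {line}: negative"
        )
    return df


def read_growth(path: str | Path) -> pd.DataFrame:
    df = read_table(path, GROWTH_COLUMNS)
    _check_positive(df, ["dilution_factor"], Path(path).name)
    if (df["od750"] < 0).any():
        bad = df["od750"] < 0
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{Path(path).name}: column 'od750', line {line}: negative"
        )
    return df
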