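"""Sample records and tabular I/O.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per sample. Chemical marker columns hold concentrations (mg/kg for
honey, mg/L for nectar) with ``NaN`` where the measurement fell below the
limit of reporting (LOR); a paired boolean column ``<marker>_cens`` carries
the censor flag. DNA marker columns hold Cq values and are never censored
(values above the Cq LOR are retained as measured, up to the assay maximum).

On disk the tables are plain CSV. Censored chemical cells are serialized as
the literal string ``"<LOR"`` and the flag columns are dropped; reading the
CSV reconstructs the flags, so a round trip preserves censoring exactly.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import (
    CHEMICAL_MARKERS,
    DNA_MARKERS,
    HoneyType,
    marker_kind,
    MarkerKind,
)

#: Metadata columns of a honey table, in output order.
HONEY_META_COLUMNS = (
    "sample_id",
    "supplier_label",
    "true_class",
    "region",
    "island",
    "year",
    "country",
)

NECTAR_META_COLUMNS = (
    "sample_id",
    "species",
    "region",
    "habitat",
    "sugar_content",
)

CENSOR_SUFFIX = "_cens"


def censor_col(marker: str) -> str:
    """Name of the boolean censor-flag column paired with ``marker``."""
    return marker + CENSOR_SUFFIX


@dataclass
class HoneySample:
    """One honey specimen: marker panel plus supplier and origin metadata."""

    sample_id: str
    supplier_label: HoneyType
    true_class: HoneyType
    marker_values: dict[str, float]
    censored: dict[str, bool] = field(default_factory=dict)
    region: str = ""
    island: str = ""
    year: str = ""
    country: str = "NZ"

    def value(self, marker: str) -> float:
        return self.marker_values[marker]

    def is_censored(self, marker: str) -> bool:
        return bool(self.censored.get(marker, False))


@dataclass
class NectarSample:
    """One nectar specimen: marker panel (mg/L), sugar content and habitat."""

    sample_id: str
    species: str
    marker_values: dict[str, float]
    censored: dict[str, bool] = field(default_factory=dict)
    sugar_content: float = 80.0
    region: str = ""
    habitat: str = ""


def marker_columns(df: pd.DataFrame) -> list[str]:
    """Marker columns present in a sample table, registry order."""
    return [m for m in CHEMICAL_MARKERS + DNA_MARKERS if m in df.columns]


def write_csv(df: pd.DataFrame, path: str | Path | io.TextIOBase) -> None:
    """Write a sample table to CSV with censored cells as ``"<LOR"``.

    Censor-flag columns are folded into the value columns and not written.
    """
    out = df.copy()
    for m in marker_columns(out):
        flag = censor_col(m)
        if flag in out.columns:
            vals = out[m].astype(object)
            vals[out[flag].astype(bool)] = "<LOR"
            out[m] = vals
            out = out.drop(columns=[flag])
    out.to_csv(path, index=False)


def read_csv(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a sample CSV, reconstructing censor flags from ``"<LOR"`` cells."""
    df = pd.read_csv(path)
    for m in marker_columns(df):
        if df[m].dtype == object:
            mask = df[m].astype(str).str.strip() == "<LOR"
        else:
            mask = pd.Series(False, index=df.index)
        if marker_kind(m) is MarkerKind.CHEMICAL:
            vals = pd.to_numeric(
                df[m].where(~mask), errors="coerce"
            )
            df[m] = vals
            df[censor_col(m)] = mask.to_numpy(dtype=bool)
        else:
            df[m] = pd.to_numeric(df[m], errors="coerce")
    return df


def validate_schema(df: pd.DataFrame, required_markers: list[str]) -> None:
    """Raise ``SchemaError`` naming the first missing required column."""
    for col in required_markers:
        if col not in df.columns:
            raise SchemaError(f"input table is missing required column {col!r}")
    for m in required_markers:
        if m in df.columns and marker_kind(m) is MarkerKind.CHEMICAL:
            flag = censor_col(m)
            if flag in df.columns:
                bad = df[m].isna() & ~df[flag].astype(bool)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise SchemaError(
                        f"column {m!r} has a missing value at row {row} "
                        "that is not flagged censored"
                    )


class SchemaError(ValueError):
    """An input table does not match the documented CSV schema."""
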