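"""Reading and writing gel-observation tables and result reports.

The on-disk table format is plain CSV (UTF-8, decimal point, ``#`` comment
lines) with header

    name,d_min_nm,d_max_nm,d_avg_nm,cl,l_nm,m_values

where ``m_values`` is a semicolon-separated list of integers and ``cl`` /
``l_nm`` may be either a scalar or a ``lo;hi`` range. Reports are CSV files
preceded by a ``#``-commented metadata header (version, effective
configuration, timestamp).
"""

from __future__ import annotations

import datetime
import importlib.resources
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .chains import DomainError
from .spontaneous import GelObservation

__all__ = [
    "SchemaError",
    "bundled_observations",
    "read_gel_table",
    "write_report",
]

logger = logging.getLogger(__name__)

GEL_TABLE_COLUMNS = [
    "name",
    "d_min_nm",
    "d_max_nm",
    "d_avg_nm",
    "cl",
    "l_nm",
    "m_values",
]


class SchemaError(ValueError):
    """The input file does not match the documented table schema."""


def _parse_scalar_or_range(cell, column: str, row_label: str):
    """Parse a cell that is either a number or a semicolon 'lo;hi' range."""
    text = str(cell).strip()
    parts = [p for p in text.split(";") if p != ""]
    try:
        values = [float(p) for p in parts]
    except ValueError as exc:
        raise SchemaError(
            f"{row_label}: non-numeric value {text!r} in column {column!r}"
        ) from exc
    if len(values) == 1:
        return values[0]
    if len(values) == 2:
        return (values[0], values[1])
    raise SchemaError(
        f"{row_label}: column {column!r} must be a scalar or 'lo;hi', got {text!r}"
    )


def _parse_m_values(cell, row_label: str) -> list[int]:
    parts = [p for p in str(cell).strip().split(";") if p != ""]
    try:
        return [int(float(p)) for p in parts]
    except ValueError as exc:
        raise SchemaError(
            f"{row_label}: non-integer coordination in m_values {cell!r}"
        ) from exc


def read_gel_table(path) -> list[GelObservation]:
    """Read a gel-observation CSV into validated `GelObservation` records.

    Raises
    ------
    SchemaError
        On a missing column, a non-numeric cell, or a row violating the
        observation invariants; messages name the offending row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty (no header)") from exc
    missing = [c for c in GEL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if frame.empty:
        logger.warning("%s: table has a header but no data rows", path)
        return []

    observations = []
    for idx, row in frame.iterrows():
        label = f"{path.name} row {idx + 2}"  # 1-based, counting the header
        try:
            obs = GelObservation(
                name=str(row["name"]).strip(),
                d_min=float(row["d_min_nm"]),
                d_max=float(row["d_max_nm"]),
                d_avg=float(row["d_avg_nm"]),
                cl=_parse_scalar_or_range(row["cl"], "cl", label),
                l=_parse_scalar_or_range(row["l_nm"], "l_nm", label),
                m_values=_parse_m_values(row["m_values"], label),
            )
        except (ValueError, DomainError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{label}: {exc}") from exc
        observations.append(obs)
    return observations


def bundled_observations() -> list[GelObservation]:
    """The packaged literature table of spontaneous-penetration observations."""
    resource = importlib.resources.files("biogel.data") / "table1.csv"
    with importlib.resources.as_file(resource) as path:
        return read_gel_table(path)


def write_report(
    table: pd.DataFrame,
    path,
    metadata: dict | None = None,
    timestamp: bool = True,
) -> None:
    """Write a tidy result table as CSV with a ``#``-commented metadata header.

    Column and row order are preserved exactly as given, so reruns with the
    same configuration are byte-identical apart from the timestamp line
    (suppress it with ``timestamp=False``).
    """
    path = Path(path)
    lines = [f"# biogel {__version__}"]
    if timestamp:
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        lines.append(f"# timestamp: {stamp}")
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w", encoding="utf-8") as handle:
        for line in lines:
            handle.write(line + "\n")
        table.to_csv(handle, index=False)
    logger.info("wrote %d rows to %s", len(table), path)
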