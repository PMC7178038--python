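"""Delimited-table and FASTA readers/writers with schema validation.

Tables are comma- or tab-separated text with a header row; the delimiter
is auto-detected.  ``read_table`` validates the header against a schema
(column name -> dtype) and reports the offending column and line number on
failure.  Decimal commas are rejected explicitly rather than silently
parsed as strings.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ParseError",
    "read_table",
    "write_table",
    "read_fasta",
    "PEAK_TABLE_SCHEMA",
    "read_peak_table",
    "write_peak_table",
]

#: Schema of the per-residue peak-decay table.
PEAK_TABLE_SCHEMA: Mapping[str, type] = {
    "residue_index": int,
    "residue": str,
    "time_min": float,
    "height": float,
    "pD": float,
    "temperature_K": float,
}

_DECIMAL_COMMA = re.compile(r"^\s*-?\d+,\d+\s*$")


class ParseError(ValueError):
    """Input-table parse/validation failure, naming column and line."""


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_table(path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a delimited text table and validate it against ``schema``.

    Raises :class:`ParseError` naming the column (and 1-based data line)
    for missing columns, decimal commas, or unconvertible values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, comment="#",
                     skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    out = {}
    for col, dtype in schema.items():
        raw = df[col].astype(str)
        if dtype in (int, float):
            commas = raw.str.match(_DECIMAL_COMMA)
            if commas.any():
                line = int(np.flatnonzero(commas.to_numpy())[0]) + 2  # + header
                raise ParseError(
                    f"{path.name}: column {col!r}, line {line}: decimal comma "
                    f"({raw[commas.idxmax()]!r}); use '.' as the decimal separator"
                )
        try:
            out[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path.name}: column {col!r}: {exc}") from exc
    result = pd.DataFrame(out)
    result.attrs["source"] = str(path)
    return result


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> Path:
    path = Path(path)
    df.to_csv(path, sep=sep, index=False)
    return path


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as {id: sequence}."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ParseError(f"{Path(path).name}: no FASTA records found")
    return records


def read_peak_table(path):
    """Peak-decay table -> list of :class:`~thermofold.hdx.PeakDecaySeries`.

    Expects one row per (residue, time) with the :data:`PEAK_TABLE_SCHEMA`
    columns; series are grouped by residue and pD.
    """
    from .hdx import PeakDecaySeries

    df = read_table(path, PEAK_TABLE_SCHEMA)
    series = []
    for (idx, aa, pD, temp), grp in df.groupby(
        ["residue_index", "residue", "pD", "temperature_K"], sort=True
    ):
        grp = grp.sort_values("time_min")
        series.append(
            PeakDecaySeries(
                residue_index=int(idx),
                residue=str(aa),
                times=grp["time_min"].to_numpy(),
                heights=grp["height"].to_numpy(),
                pD=float(pD),
                temperature=float(temp),
                normalized=True,
            )
        )
    return series


def write_peak_table(series_list, path) -> Path:
    """Inverse of :func:`read_peak_table`."""
    rows = []
    for s in series_list:
        for t, h in zip(s.times, s.heights):
            rows.append(
                {
                    "residue_index": s.residue_index,
                    "residue": s.residue,
                    "time_min": t,
                    "height": h,
                    "pD": s.pD,
                    "temperature_K": s.temperature,
                }
            )
    return write_table(pd.DataFrame(rows), path)
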