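"""Readers and writers for feature tables (CSV/TSV).

Tables are features × samples: first column the feature name
(``compound`` / ``lipid`` / ``amino_acid``), remaining columns numeric.
For peak tables both empty cells and literal zeros mean "not detected"
and are normalized to missing — a zero peak area is an absence call by
the instrument software, not a measured quantity.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .names import canonicalize

KINDS = ("peaks", "lipids", "amino_acids")
_INDEX_NAMES = {"peaks": "compound", "lipids": "lipid",
                "amino_acids": "amino_acid"}


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() in (".tsv", ".tab"):
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_feature_table(path, kind: str) -> pd.DataFrame:
    """Read a feature × sample table, validating names and cells.

    Peak-table feature names are canonicalized; duplicate names (after
    canonicalization) and non-numeric cells are errors that name the
    offender.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    path = Path(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if kind == "peaks":
        raw.index = [canonicalize(c) for c in raw.index]
    else:
        raw.index = [str(c).strip() for c in raw.index]
    counts = pd.Series(raw.index).value_counts()
    dupes = list(counts[counts > 1].index)
    if dupes:
        raise ValueError(f"duplicate feature names in {path.name}: {dupes}")

    data = {}
    for col in raw.columns:
        cells = raw[col].str.strip()
        numeric = pd.to_numeric(cells.mask(cells == ""), errors="coerce")
        bad = cells.ne("") & numeric.isna()
        if bad.any():
            feat = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric cell in {path.name}: row {feat!r}, "
                f"column {col!r} = {cells[bad].iloc[0]!r}"
            )
        data[col] = numeric.to_numpy()
    table = pd.DataFrame(data, index=raw.index)
    table.index.name = _INDEX_NAMES[kind]
    if kind == "peaks":
        table = table.where(table != 0.0)  # zero area == non-detected
    return table


def write_feature_table(table: pd.DataFrame, path, kind: str,
                        decimals: int | None = None) -> None:
    """Write a feature × sample table as CSV/TSV; missing cells empty."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    path = Path(path)
    out = table.copy()
    out.index.name = _INDEX_NAMES[kind]
    if decimals is not None:
        out = out.round(decimals)
    out.to_csv(path, sep=_sniff_sep(path), na_rep="")
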