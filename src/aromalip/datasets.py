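"""Packaged reference data for the dry-cured-ham worked example.

Two small tables transcribed from the study's characteristic-volatiles
panel (28 compounds): the odor-threshold database (threshold in µg/kg,
chemical class, odor descriptor where the study states one) and the
printed relative-content / ROAV columns used as the worked example and
as regression anchors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .names import canonicalize


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("aromalip.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, keep_default_na=False)


def load_threshold_db() -> pd.DataFrame:
    """Odor-threshold database: compound, threshold_ug_per_kg,
    chemical_class, descriptor."""
    return _load("ham_odor_thresholds.csv")


def load_volatile_contents() -> pd.DataFrame:
    """Printed relative contents (C%, percent) and reported ROAVs for the
    28-compound ham panel."""
    df = _load("ham_volatile_contents.csv")
    df["relative_content_percent"] = df["relative_content_percent"].astype(float)
    df["roav_reported"] = df["roav_reported"].astype(float)
    return df


def ham_reference_records() -> pd.DataFrame:
    """The worked-example panel as scoring-ready records.

    Joins the printed relative contents with the threshold DB on
    canonical names; columns: compound, c_percent, threshold,
    chemical_class, descriptor, roav_reported.
    """
    contents = load_volatile_contents()
    db = load_threshold_db()
    contents["compound"] = contents["compound"].map(canonicalize)
    db = db.copy()
    db["compound"] = db["compound"].map(canonicalize)
    merged = contents.merge(db, on="compound", how="inner")
    if len(merged) != len(contents):
        raise RuntimeError("packaged reference tables are out of sync")
    merged = merged.rename(columns={
        "relative_content_percent": "c_percent",
        "threshold_ug_per_kg": "threshold",
    })
    return merged[["compound", "c_percent", "threshold", "chemical_class",
                   "descriptor", "roav_reported"]]
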