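"""Replicate peak-table screening for GC-MS volatile profiles.

A peak table is a compounds × replicates matrix of raw peak areas with
``NaN`` marking non-detection.  Screening proceeds in three steps before
any flavor scoring:

1. detection-rate filter — keep compounds detected in more than half the
   replicates (strict by default);
2. reproducibility filter — keep compounds whose coefficient of variation
   (sample SD / mean over the *detected* replicates) is below 30 percent
   (strict by default);
3. relative percentage content — each retained compound's mean detected
   area as a percentage of the summed mean areas of all retained
   compounds (C%), which sums to 100 by construction.

Retained compounds are then inner-joined against an odor-threshold
database; C% is deliberately **not** renormalized after that join, so the
denominator reflects the full screened volatile profile rather than only
the compounds with a published threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .names import canonicalize

logger = logging.getLogger("aromalip")


def _validate_table(table: pd.DataFrame) -> None:
    # empty compound sets are legal mid-pipeline (a filter may remove
    # everything); fewer than two replicate columns never is
    if table.shape[1] < 2:
        raise ValueError("peak table needs >= 2 samples")
    if (table.to_numpy(dtype=float) < 0).any():
        raise ValueError("peak areas must be non-negative")
    canon = [canonicalize(c) for c in table.index]
    dupes = pd.Series(canon).value_counts()
    dupes = dupes[dupes > 1]
    if len(dupes):
        raise ValueError(
            f"duplicate compounds after canonicalization: {list(dupes.index)}"
        )


def detection_stats(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-compound detection rate, mean area and CV over detected replicates.

    CV is NaN when fewer than two replicates were detected (SD undefined
    with the n−1 denominator).
    """
    n = table.shape[1]
    detected = table.notna().sum(axis=1)
    mean = table.mean(axis=1, skipna=True)
    sd = table.std(axis=1, skipna=True, ddof=ddof)
    cv = sd / mean
    cv[detected < ddof + 1] = np.nan
    return pd.DataFrame({
        "n_detected": detected,
        "detection_rate": detected / n,
        "mean_area": mean,
        "cv": cv,
    })


def detection_rate_filter(
    table: pd.DataFrame, min_rate: float = 0.5, inclusive: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep compounds detected in more than ``min_rate`` of replicates.

    Returns the filtered table and a per-compound report with the rates
    and a ``retained`` flag.  The comparison is strict (``>``) unless
    ``inclusive`` is set.
    """
    if not 0 <= min_rate <= 1:
        raise ValueError("min_rate must be in [0, 1]")
    _validate_table(table)
    stats = detection_stats(table)
    rate = stats["detection_rate"]
    keep = rate >= min_rate if inclusive else rate > min_rate
    report = stats[["n_detected", "detection_rate"]].assign(retained=keep)
    if not keep.any():
        logger.warning("detection-rate filter removed every compound")
    return table.loc[keep], report


def cv_filter(
    table: pd.DataFrame, max_cv: float = 0.30, inclusive: bool = False,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep compounds whose replicate CV is below ``max_cv``.

    CV = sample standard deviation / mean over detected replicates only.
    Compounds with an undefined CV (a single detected replicate) are
    removed and logged.  Strict (``<``) unless ``inclusive``.
    """
    if max_cv <= 0:
        raise ValueError("max_cv must be positive")
    _validate_table(table)
    stats = detection_stats(table, ddof=ddof)
    cv = stats["cv"]
    undefined = cv.isna() & (stats["n_detected"] > 0)
    for name in table.index[undefined]:
        logger.warning("compound %r: CV undefined (single replicate); removed",
                       name)
    keep = (cv <= max_cv if inclusive else cv < max_cv).fillna(False)
    report = stats[["n_detected", "cv"]].assign(retained=keep)
    if not keep.any():
        logger.warning("CV filter removed every compound")
    return table.loc[keep], report


def relative_content(table: pd.DataFrame) -> pd.DataFrame:
    """Relative percentage content (C%) of each retained compound.

    ``c_percent_i = 100 · mean_area_i / Σ_j mean_area_j`` with means over
    detected replicates; the column sums to 100 exactly over the input
    compounds.  Expects a table that already passed both filters.
    """
    _validate_table(table)
    stats = detection_stats(table)
    if stats["mean_area"].isna().any():
        missing = list(table.index[stats["mean_area"].isna()])
        raise ValueError(
            f"all-missing compounds present (should have been filtered): "
            f"{missing}"
        )
    out = stats.copy()
    out["c_percent"] = 100.0 * out["mean_area"] / out["mean_area"].sum()
    out.insert(0, "compound", [canonicalize(c) for c in table.index])
    return out.reset_index(drop=True)


def read_threshold_db(path) -> pd.DataFrame:
    """Read a threshold DB CSV (compound, threshold_ug_per_kg, chemical_class,
    descriptor) and validate it."""
    db = pd.read_csv(path, keep_default_na=False)
    required = {"compound", "threshold_ug_per_kg", "chemical_class"}
    missing = required - set(db.columns)
    if missing:
        raise ValueError(f"threshold DB missing columns: {sorted(missing)}")
    if (db["threshold_ug_per_kg"] <= 0).any():
        bad = db.loc[db["threshold_ug_per_kg"] <= 0, "compound"].tolist()
        raise ValueError(f"non-positive thresholds for: {bad}")
    return db


def join_thresholds(
    screened: pd.DataFrame, db: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Inner-join screened compounds with their odor-threshold records.

    Both sides are matched on canonicalized names.  Compounds without a
    threshold annotation are dropped and returned in the report list; C%
    is not renormalized after the drop.  Duplicate DB entries for one
    compound are an error.
    """
    db = db.copy()
    db["compound"] = db["compound"].map(canonicalize)
    dupes = db["compound"].value_counts()
    dupes = dupes[dupes > 1]
    if len(dupes):
        raise ValueError(
            f"duplicate threshold records for: {list(dupes.index)}"
        )
    screened = screened.copy()
    screened["compound"] = screened["compound"].map(canonicalize)
    annotated = screened.merge(db, on="compound", how="inner")
    dropped = sorted(set(screened["compound"]) - set(annotated["compound"]))
    if dropped:
        logger.info("%d compounds lack a threshold annotation: %s",
                    len(dropped), dropped)
    annotated = annotated.rename(columns={"threshold_ug_per_kg": "threshold"})
    return annotated, dropped


def kovats_ri(retention_time: float, alkane_times: dict[int, float]) -> float:
    """Kovats retention index by linear interpolation on an n-alkane ladder.

    ``RI = 100·n + 100·(t − t_n)/(t_{n+1} − t_n)`` for temperature-
    programmed runs; the retention time must be bracketed by (or sit on)
    two consecutive ladder alkanes.
    """
    carbons = sorted(alkane_times)
    times = [alkane_times[c] for c in carbons]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("alkane times must increase strictly with carbons")
    for n, t_n, t_next in zip(carbons, times, times[1:]):
        if t_n <= retention_time <= t_next:
            frac = (retention_time - t_n) / (t_next - t_n)
            return 100.0 * n + 100.0 * frac
    if retention_time == times[-1]:
        return 100.0 * carbons[-1]
    raise ValueError(
        f"retention time {retention_time} not bracketed by the alkane "
        f"ladder (C{carbons[0]} at {times[0]} … C{carbons[-1]} at "
        f"{times[-1]})"
    )
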