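"""Relative odor activity value (ROAV) scoring and classification.

ROAV ranks volatiles by flavor contribution relative to the single most
contributory compound (the "standard").  With C% the relative percentage
content and T the odor threshold (µg/kg), the standard is the compound
maximizing C%/T, its ROAV is defined as 100, and every other compound A
scores

    ROAV_A = 100 · (C%_A / C%_stan) · (T_stan / T_A)

so 0 < ROAV ≤ 100.  Compounds with ROAV ≥ 1 are characteristic flavor
compounds; 0.1 ≤ ROAV < 1 marks flavor modifiers; below 0.1 the
contribution is negligible.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("aromalip")

CHARACTERISTIC_CUTOFF = 1.0
MODIFIER_CUTOFF = 0.1


def _check_records(records: pd.DataFrame) -> None:
    for col in ("compound", "c_percent", "threshold"):
        if col not in records.columns:
            raise ValueError(f"records missing required column {col!r}")
    if len(records) == 0:
        raise ValueError("no annotated compounds to score")
    bad = records.loc[records["threshold"] <= 0, "compound"].tolist()
    if bad:
        raise ValueError(f"non-positive odor threshold for: {bad}")


def select_standard(records: pd.DataFrame) -> str:
    """Name of the maximum-contribution compound (argmax of C%/T).

    Ties are broken by canonical name order and logged.
    """
    _check_records(records)
    ratio = records["c_percent"] / records["threshold"]
    best = ratio.max()
    winners = sorted(records.loc[ratio == best, "compound"])
    if len(winners) > 1:
        logger.warning("standard-selection tie between %s; taking %r",
                       winners, winners[0])
    return winners[0]


def compute_roav(records: pd.DataFrame, standard: str | None = None
                 ) -> pd.DataFrame:
    """Score every compound against the standard.

    ``standard=None`` selects it as argmax C%/T, in which case all scores
    are ≤ 100.  The standard's ROAV is exactly 100 by definition.
    """
    _check_records(records)
    if standard is None:
        standard = select_standard(records)
    mask = records["compound"] == standard
    if not mask.any():
        raise ValueError(f"standard {standard!r} not among the records")
    c_stan = float(records.loc[mask, "c_percent"].iloc[0])
    t_stan = float(records.loc[mask, "threshold"].iloc[0])
    if c_stan <= 0:
        raise ValueError(f"standard {standard!r} has non-positive C%")
    out = records.copy()
    out["roav"] = (
        100.0 * (out["c_percent"] / c_stan) * (t_stan / out["threshold"])
    )
    out.loc[mask, "roav"] = 100.0
    out["is_standard"] = mask.to_numpy()
    return out


def classify_contribution(
    records: pd.DataFrame,
    characteristic_cutoff: float = CHARACTERISTIC_CUTOFF,
    modifier_cutoff: float = MODIFIER_CUTOFF,
) -> pd.DataFrame:
    """Attach the three-way contribution category.

    characteristic: ROAV ≥ 1; modifier: 0.1 ≤ ROAV < 1; negligible
    otherwise.  Both boundaries are inclusive on the lower side.
    """
    if not 0 < modifier_cutoff < characteristic_cutoff:
        raise ValueError("cutoffs must satisfy 0 < modifier < characteristic")
    out = records.copy()
    roav = out["roav"]
    out["category"] = np.select(
        [roav >= characteristic_cutoff, roav >= modifier_cutoff],
        ["characteristic", "modifier"],
        default="negligible",
    )
    counts = out["category"].value_counts().to_dict()
    logger.info("contribution categories: %s", counts)
    return out


def largest_remainder_shares(counts: Mapping[str, int]) -> dict[str, int]:
    """Integer percentage shares summing to exactly 100.

    Hamilton/largest-remainder apportionment: floor each exact share, then
    hand the leftover points to the largest fractional remainders, ties
    broken by descending count then name.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    exact = {k: 100.0 * v / total for k, v in counts.items()}
    shares = {k: int(np.floor(x)) for k, x in exact.items()}
    leftover = 100 - sum(shares.values())
    order = sorted(
        counts,
        key=lambda k: (-(exact[k] - shares[k]), -counts[k], k),
    )
    for k in order[:leftover]:
        shares[k] += 1
    return shares


def class_composition(
    records: pd.DataFrame | Mapping[str, int],
    classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Chemical-class counts and integer percent shares (sum = 100).

    ``records`` is either a scored DataFrame (class taken from its
    ``chemical_class`` column, or from the ``classes`` map with
    unmapped compounds assigned "other" and logged) or a ready-made
    class → count mapping.
    """
    if isinstance(records, Mapping):
        counts = dict(records)
    else:
        if classes is not None:
            assigned = []
            for name in records["compound"]:
                if name not in classes:
                    logger.warning("compound %r has no class; using 'other'",
                                   name)
                assigned.append(classes.get(name, "other"))
        elif "chemical_class" in records.columns:
            assigned = records["chemical_class"].tolist()
        else:
            raise ValueError("no chemical-class information provided")
        counts = pd.Series(assigned).value_counts().to_dict()
    shares = largest_remainder_shares(counts)
    df = pd.DataFrame({
        "chemical_class": list(counts),
        "count": [counts[k] for k in counts],
        "percent_share": [shares[k] for k in counts],
    })
    return df.sort_values(
        ["count", "chemical_class"], ascending=[False, True]
    ).reset_index(drop=True)
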