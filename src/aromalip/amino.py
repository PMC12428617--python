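"""Taste annotation and key selection for free amino acids.

Free amino acids are non-volatile flavor compounds; each is dominated by
one taste class (sweet, bitter, umami, neutral, or the mixed
sweet-bitter of L-lysine).  The default map covers the 20 proteinogenic
amino acids plus L-ornithine, L-citrulline, 4-aminobutyric acid and
beta-alanine and can be overridden wholesale.  Key amino acids are
those whose mean relative content reaches a cutoff (default 40, on the
same scale as the input table; the boundary is inclusive).
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

logger = logging.getLogger("aromalip")

TASTE_CLASSES = ("sweet", "bitter", "umami", "neutral", "sweet-bitter")
KEY_CONTENT_CUTOFF = 40.0


def load_default_taste_map() -> dict[str, str]:
    """Packaged amino acid → taste class map."""
    ref = resources.files("aromalip.data") / "taste_map_default.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return dict(zip(df["amino_acid"], df["taste_class"]))


def annotate_taste(
    table: pd.DataFrame, taste_map: dict[str, str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Annotate an amino acid × sample table with taste classes.

    Returns a tidy frame (amino_acid, relative_content, taste_class)
    where relative_content is the mean over sample columns.  Unknown
    amino acids raise in strict mode, otherwise get class "unknown".
    """
    taste_map = load_default_taste_map() if taste_map is None else taste_map
    bad = [c for c in taste_map.values() if c not in TASTE_CLASSES]
    if bad:
        raise ValueError(f"invalid taste classes in map: {sorted(set(bad))}")
    unknown = [n for n in table.index if n not in taste_map]
    if unknown and strict:
        raise KeyError(f"amino acids missing from the taste map: {unknown}")
    if unknown:
        logger.warning("unmapped amino acids annotated 'unknown': %s",
                       unknown)
    return pd.DataFrame({
        "amino_acid": table.index,
        "relative_content": table.mean(axis=1, skipna=True).to_numpy(),
        "taste_class": [taste_map.get(n, "unknown") for n in table.index],
    }).reset_index(drop=True)


def select_key(
    records: pd.DataFrame, min_content: float = KEY_CONTENT_CUTOFF
) -> pd.DataFrame:
    """Flag key amino acids: relative content ≥ ``min_content`` (inclusive).

    Output is ranked by content (descending, name tie-break) so the top
    row names the most abundant amino acid.
    """
    if min_content < 0:
        raise ValueError("min_content must be >= 0")
    out = records.copy()
    out["is_key"] = out["relative_content"] >= min_content
    out = out.sort_values(
        ["relative_content", "amino_acid"], ascending=[False, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    logger.info("%d key amino acids (cutoff %.3g); top: %s",
                int(out["is_key"].sum()), min_content,
                out["amino_acid"].iloc[0] if len(out) else "n/a")
    return out
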