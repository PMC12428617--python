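"""Cross-block Pearson correlation of flavor precursors against volatiles.

Correlates every feature of one block (lipids or free amino acids)
against every feature of another (characteristic volatiles) across the
shared samples, the structure behind precursor–flavor heatmaps.  r and
the two-sided p-value come from the exact t transform
``t = r·√((n−2)/(1−r²))`` on pairwise-complete observations;
Benjamini–Hochberg FDR adjustment across the full pair grid is on by
default since such grids routinely hold hundreds of tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("aromalip")


def _drop_zero_variance(block: pd.DataFrame, label: str) -> pd.DataFrame:
    variances = block.var(axis=1, skipna=True, ddof=1)
    flat = variances.fillna(0.0) == 0.0
    if flat.any():
        logger.warning("excluding zero-variance %s features: %s",
                       label, list(block.index[flat]))
    return block.loc[~flat]


def block_correlate(
    block_a: pd.DataFrame, block_b: pd.DataFrame, method: str = "pearson",
    adjust: str = "bh", min_n: int = 3,
) -> pd.DataFrame:
    """All pairwise correlations between two feature × sample blocks.

    Samples are intersected by column name (at least ``min_n`` shared
    required); r is computed on pairwise-complete observations, pairs
    with fewer than ``min_n`` complete observations are suppressed.
    ``adjust`` is "bh" (Benjamini–Hochberg over all reported pairs) or
    "none".
    """
    if method != "pearson":
        raise ValueError(f"unsupported correlation method {method!r}")
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")
    shared = [s for s in block_a.columns if s in set(block_b.columns)]
    if len(shared) < min_n:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= {min_n}"
        )
    if len(shared) <= 4:
        logger.warning(
            "only %d shared samples: p-values have very low power",
            len(shared),
        )
    a = _drop_zero_variance(block_a[shared], "block-a")
    b = _drop_zero_variance(block_b[shared], "block-b")
    rows = []
    for fa in a.index:
        xa = a.loc[fa].to_numpy(dtype=float)
        for fb in b.index:
            xb = b.loc[fb].to_numpy(dtype=float)
            ok = ~(np.isnan(xa) | np.isnan(xb))
            n = int(ok.sum())
            if n < min_n:
                logger.warning("pair (%s, %s): only %d complete samples; "
                               "suppressed", fa, fb, n)
                continue
            res = stats.pearsonr(xa[ok], xb[ok])
            r = float(res.statistic)
            p = float(res.pvalue)
            # exact affine dependence accumulates ~n·ε rounding in the
            # dot product; snap so perfect dependence reports |r| = 1
            if 1.0 - abs(r) < 1e-12:
                r = float(np.copysign(1.0, r))
                p = 0.0
            rows.append({
                "feature_a": fa, "feature_b": fb, "r": r, "n": n,
                "p_value": p,
                "sign": "positive" if r > 0 else
                        "negative" if r < 0 else "zero",
            })
    out = pd.DataFrame(
        rows,
        columns=["feature_a", "feature_b", "r", "n", "p_value", "sign"],
    )
    if adjust == "bh" and len(out):
        out["p_adjusted"] = multipletests(
            out["p_value"].to_numpy(), method="fdr_bh"
        )[1]
    else:
        out["p_adjusted"] = out["p_value"] if len(out) else []
    return out[["feature_a", "feature_b", "r", "n",
                "p_value", "p_adjusted", "sign"]]


def export_heatmap_matrix(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot long-form results into an r matrix and a p-adjusted matrix.

    Row/column order follows first appearance in the input (no
    clustering); requires the complete pair grid.
    """
    row_order = list(dict.fromkeys(results["feature_a"]))
    col_order = list(dict.fromkeys(results["feature_b"]))
    r = results.pivot(index="feature_a", columns="feature_b", values="r")
    p = results.pivot(index="feature_a", columns="feature_b",
                      values="p_adjusted")
    r = r.reindex(index=row_order, columns=col_order)
    p = p.reindex(index=row_order, columns=col_order)
    if r.isna().any().any():
        raise ValueError("incomplete pair grid; cannot form a full matrix")
    return r, p
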