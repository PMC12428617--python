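"""Parse and classify lipid species; aggregate shares and key lipids.

Parses the 14-species key-lipid panel, then annotates the simulated
lipid table: class/category shares and the top-14 key lipids by mean
relative abundance.  Run 01_simulate_tables.py first.
"""

import pandas as pd

import aromalip as al
from aromalip.io import read_feature_table
from _paths import RESULTS

OUT = RESULTS / "lipids"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in al.KEY_HAM_LIPIDS:
        sp = al.parse_lipid(name)
        rows.append({
            "lipid": al.format_lipid(sp), "class_code": sp.class_code,
            "category": sp.category, "sum_carbons": sp.sum_carbons,
            "sum_double_bonds": sp.sum_double_bonds,
            "extra_oxygens": sp.sum_extra_oxygens,
            "n_chains": len(sp.chains),
            "sn_known": sp.sn_positions_known,
        })
    panel = pd.DataFrame(rows)
    panel.to_csv(OUT / "key_lipid_panel_annotated.csv", index=False)
    print(f"key-lipid panel: {len(panel)} names, all parsed; categories: "
          f"{panel['category'].value_counts().to_dict()}")

    table = read_feature_table(RESULTS / "synthetic" / "lipids.csv", "lipids")
    for level in ("category", "class_code"):
        shares = al.class_shares(table, level)
        shares.to_csv(OUT / f"shares_{level}.csv", index=False)
        head = ", ".join(
            f"{r[level]} {r['share_percent']:.2f}%"
            for _, r in shares.head(5).iterrows())
        print(f"{level} shares (top 5): {head}")
    key = al.select_key_lipids(table, top_n=14)
    key.to_csv(OUT / "key_lipids.csv", index=False)
    print(f"top key lipid by mean abundance: {key['lipid'].iloc[0]} "
          f"({key['mean_abundance'].iloc[0]:.3f})")


if __name__ == "__main__":
    main()
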