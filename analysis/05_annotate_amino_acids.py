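"""Taste-annotate free amino acids and select the key ones.

Annotates the simulated free-amino-acid table with taste classes and
flags key amino acids (mean relative content >= 40, inclusive).  Run
01_simulate_tables.py first.
"""

import aromalip as al
from aromalip.io import read_feature_table
from _paths import RESULTS

OUT = RESULTS / "amino_acids"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(
        RESULTS / "synthetic" / "amino_acids.csv", "amino_acids")
    records = al.select_key(al.annotate_taste(table))
    records.to_csv(OUT / "amino_acids_annotated.csv", index=False)

    keys = records[records["is_key"]]
    print(f"{len(records)} free amino acids; {len(keys)} key "
          f"(content >= 40)")
    print("key amino acids, ranked:")
    for _, row in keys.iterrows():
        print(f"  {row['rank']:>2d}. {row['amino_acid']:<18s} "
              f"{row['relative_content']:7.2f}  ({row['taste_class']})")
    by_taste = records.groupby("taste_class")["relative_content"].sum()
    print(f"dominant taste class by total content: {by_taste.idxmax()}")


if __name__ == "__main__":
    main()
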