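"""Simulate the study's data layer with known ground truth.

Generates a 4-replicate GC-MS peak table whose true relative contents
follow the 28-compound ham panel (plus a bulk unannotated compound),
a shorthand lipid table with class frequencies echoing the dominant
subclasses reported for dry-cured ham, and a free amino-acid table.
Everything lands under results/synthetic/ with JSON truth sidecars.
"""

import numpy as np

import aromalip as al
from aromalip.synthetic import export_with_truth
from _paths import RESULTS

SEED = 20240901
OUT = RESULTS / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = al.ham_reference_records()
    proportions = dict(panel.set_index("compound")["c_percent"] / 100.0)
    proportions["bulk unannotated matrix"] = 1.0 - sum(proportions.values())
    spec = al.SyntheticSpec(
        n_compounds=len(proportions),
        n_replicates=4,
        true_relative_content=np.array(list(proportions.values())),
        replicate_cv=0.15,
        dropout_prob=0.05,
        seed=SEED,
        compounds=list(proportions),
    )
    peaks = al.generate_peak_table(spec)
    export_with_truth(peaks, OUT / "peaks.csv", {
        "seed": SEED, "replicate_cv": 0.15, "dropout_prob": 0.05,
        "true_relative_content": proportions,
    })
    print(f"peak table: {peaks.shape[0]} compounds x "
          f"{peaks.shape[1]} replicates, "
          f"{int(peaks.isna().sum().sum())} non-detections")

    weights = {"TG": 25.29, "DG": 13.43, "DGCC": 8.47, "DGTS": 6.26,
               "MGDG": 6.06, "PC": 5.0, "PE": 4.0, "SM": 4.0, "Cer": 3.0,
               "SHexCer": 2.0, "PE-Cer": 2.0, "FAHFA": 1.5, "NAGly": 1.0,
               "ST": 1.0}
    lipids = al.generate_lipid_table(400, weights, seed=SEED, n_samples=4)
    lipids.columns = peaks.columns
    export_with_truth(lipids, OUT / "lipids.csv",
                      {"seed": SEED, "subclass_weights": weights})
    print(f"lipid table: {lipids.shape[0]} species; "
          f"all names parse: "
          f"{all(al.parse_lipid(n) is not None for n in lipids.index)}")

    amino = al.generate_amino_table(cv=0.1, n_samples=4, seed=SEED)
    amino.columns = peaks.columns
    export_with_truth(amino, OUT / "amino_acids.csv", {"seed": SEED})
    print(f"amino-acid table: {amino.shape[0]} amino acids; "
          f"most abundant: {amino.mean(axis=1).idxmax()}")


if __name__ == "__main__":
    main()
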