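"""Train and evaluate the four model variants.

Gradient-boosted classification of cancer vs healthy on a stratified 70/30
split: M1 all VOCs, M2 screened biomarkers (training fold only), M3
environmentally nondifferential VOCs, M4 breath + synthetic environment
features.  Writes one report per variant and a comparison table.
"""

import json
from pathlib import Path

import pandas as pd

from breathvoc.classify import SplitSpec, run_variant
from breathvoc.cohort import read_table

OUT = Path("results/analysis")


def main() -> None:
    breath = read_table(OUT / "breath.tsv")
    background = read_table(OUT / "background.tsv")

    rows = []
    for variant in ("M1", "M2", "M3", "M4"):
        rep = run_variant(variant, breath, background=background,
                          split=SplitSpec(train_fraction=0.70, seed=1))
        (OUT / f"model_{variant}.json").write_text(json.dumps(rep.to_dict(), indent=1))
        rows.append({"variant": variant, "n_features": len(rep.features),
                     "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
                     "specificity": rep.specificity, "auc": rep.auc})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "model_comparison.tsv", sep="\t", index=False, float_format="%.4f")
    print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
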