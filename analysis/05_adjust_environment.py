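"""Environmental adjustment: SMOTE augmentation and panel restriction.

Synthesizes one site-matched ambient VOC vector per participant by SMOTE
interpolation over that site's background-air samples and writes the
augmented (breath + environment) feature table; also writes the table
restricted to the environmentally nondifferential panel.
"""

from pathlib import Path

import pandas as pd

from breathvoc.cohort import read_table, voc_columns, write_table
from breathvoc.envadjust import SmoteConfig, assign_environment, restrict_to_nondifferential

OUT = Path("results/analysis")


def main() -> None:
    breath = read_table(OUT / "breath.tsv")
    background = read_table(OUT / "background.tsv")
    site_screen = pd.read_csv(OUT / "screen_site.tsv", sep="\t")

    augmented = assign_environment(breath, background, SmoteConfig(k_neighbors=5, seed=1))
    write_table(augmented, OUT / "augmented.tsv")
    n_env = sum(c.startswith("env_") for c in augmented.columns)
    print(f"augmented table: {len(augmented)} participants, "
          f"{len(voc_columns(breath))} breath + {n_env} environment features")

    keep = site_screen.loc[site_screen["nondifferential_all"], "voc_id"].tolist()
    restricted = restrict_to_nondifferential(breath, keep)
    write_table(restricted, OUT / "restricted.tsv")
    print(f"restricted table: {len(voc_columns(restricted))} environmentally "
          "nondifferential VOCs kept")


if __name__ == "__main__":
    main()
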