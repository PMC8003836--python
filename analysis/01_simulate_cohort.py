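"""Generate the synthetic two-site study cohort.

Writes the breath table (148 cancer cases at the hospital, 112 + 56 healthy
controls at campus / hospital), the background-air table (18 + 29 ambient
samples), and the planted ground truth used by later recovery checks.
"""

from pathlib import Path

from breathvoc.cohort import SimConfig, simulate_study, voc_columns, write_table

OUT = Path("results/analysis")


def main() -> None:
    cfg = SimConfig(seed=1)
    breath, background, truth = simulate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(breath, OUT / "breath.tsv")
    write_table(background, OUT / "background.tsv")
    truth.to_json(OUT / "ground_truth.json")

    print(f"breath samples: {len(breath)} "
          f"({(breath['group'] == 'cancer').sum()} cancer, "
          f"{(breath['group'] == 'healthy').sum()} healthy)")
    print(f"background-air samples: {len(background)} "
          f"({(background['site'] == 'campus').sum()} campus, "
          f"{(background['site'] == 'hospital').sum()} hospital)")
    print(f"VOC panel: {len(voc_columns(breath))} compounds; "
          f"{len(truth.disease_vocs)} planted disease VOCs, "
          f"{len(truth.env_differential_vocs)} site-differential ambient VOCs")


if __name__ == "__main__":
    main()
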