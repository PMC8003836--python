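"""Triple-test screens with Bonferroni correction.

Cancer-vs-healthy on breath samples (biomarker consensus) and
campus-vs-hospital on background air (environmentally nondifferential set),
each VOC tested with Wilcoxon rank-sum, pooled t, and Welch t against the
family threshold 0.05/116.  Reports recovery against the planted truth.
"""

import json
from pathlib import Path

from breathvoc.cohort import GroundTruth, read_table
from breathvoc.screen import screen_biomarkers, screen_env_nondifferential

OUT = Path("results/analysis")


def main() -> None:
    breath = read_table(OUT / "breath.tsv")
    background = read_table(OUT / "background.tsv")
    truth = GroundTruth.from_json(OUT / "ground_truth.json")

    group = screen_biomarkers(breath)
    site = screen_env_nondifferential(background)
    group.to_frame().to_csv(OUT / "screen_group.tsv", sep="\t", index=False, float_format="%.10g")
    site.to_frame().to_csv(OUT / "screen_site.tsv", sep="\t", index=False, float_format="%.10g")
    (OUT / "screen_summary.json").write_text(
        json.dumps({"group": group.summary(), "site": site.summary()}, indent=1))

    planted = set(truth.disease_vocs)
    recovered = group.biomarker_set & planted
    print(f"Bonferroni threshold: {group.threshold:.4g} (0.05/{group.m_tests})")
    print(f"significant VOCs (all three tests): {len(group.biomarker_set)}; "
          f"recovered {len(recovered)}/{len(planted)} planted disease VOCs")
    nd = site.nondifferential_set
    env_planted = set(truth.env_differential_vocs)
    print(f"environmentally nondifferential VOCs: {len(nd)}; "
          f"excluded {len(env_planted - nd)}/{len(env_planted)} planted site-differential VOCs")


if __name__ == "__main__":
    main()
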