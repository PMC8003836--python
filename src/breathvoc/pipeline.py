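"""End-to-end orchestration: simulate/load -> screen -> cluster -> adjust -> classify.

``run_all`` owns the on-disk layout and provenance.  Every stochastic stage
receives a sub-seed derived from the global seed by a fixed counter scheme,
so a stage re-run in isolation reproduces its in-pipeline output, and a rerun
of the whole pipeline under one config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SplitSpec, XgbParams, run_variant, VARIANTS
from .cluster import cluster_table, export_heatmap_bundle
from .cohort import (GROUPS, SITES, TYPES, SimConfig, read_table, simulate_study,
                     voc_columns, write_table)
from .envadjust import SmoteConfig
from .screen import screen_biomarkers, screen_env_nondifferential
from .siftms import InvalidInputError

# fixed counter scheme for stage sub-seeds
_STAGE_OFFSETS = {"simulate": 0, "smote": 1, "split": 2}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    breath_path: str | None = None
    background_path: str | None = None
    alpha_family: float = 0.05
    pseudocount: float = 0.001
    distance: str = "euclidean"
    linkage: str = "complete"
    smote_k: int = 5
    train_fraction: float = 0.70
    stratified: bool = True
    xgb: XgbParams = field(default_factory=XgbParams)
    decision_threshold: float = 0.5
    full_dataset_screen: bool = False
    seed: int = 0
    out_dir: str = "results/run"

    def validate(self) -> None:
        if not self.simulate:
            for p in (self.breath_path, self.background_path):
                if p is None:
                    raise InvalidInputError(
                        "simulation is off: breath_path and background_path are required")
                if not Path(p).exists():
                    raise InvalidInputError(f"input path does not exist: {p}")

    def config_hash(self) -> str:
        def default(o):
            return asdict(o)
        fields = asdict(self)
        fields.pop("out_dir")  # output location does not affect results
        blob = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_table(path: str | Path) -> dict:
    """Schema check of a wide sample TSV: header, enums, non-negativity."""
    problems: list[str] = []
    df = read_table(path)
    for col in ("sample_id", "group", "site", "type"):
        if col not in df.columns:
            problems.append(f"missing column: {col}")
    if not problems:
        bad_group = sorted(set(df["group"].unique()) - set(GROUPS) - {"none"})
        if bad_group:
            problems.append(f"unknown group label(s) {bad_group}; allowed: {list(GROUPS) + ['none']}")
        bad_site = sorted(set(df["site"].unique()) - set(SITES))
        if bad_site:
            problems.append(f"unknown site label(s) {bad_site}; allowed: {list(SITES)}")
        bad_type = sorted(set(df["type"].unique()) - set(TYPES))
        if bad_type:
            problems.append(f"unknown type label(s) {bad_type}; allowed: {list(TYPES)}")
        vocs = voc_columns(df)
        if not vocs:
            problems.append("no VOC columns")
        else:
            vals = df[vocs].to_numpy(dtype=float)
            rows, cols = np.where(vals < 0)
            for r, c in zip(rows[:10], cols[:10]):
                problems.append(f"negative concentration at row {r} column {vocs[c]}")
    return {"path": str(path), "passed": not problems, "problems": problems}


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a manifest dict (also written to ``manifest.json``) with stage
    seeds, config hash and the headline numbers.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs
    if config.simulate:
        sim = SimConfig(**{**asdict(config.sim), "seed": stage_seed(config.seed, "simulate")})
        breath, background, truth = simulate_study(sim)
        write_table(breath, out / "breath.tsv")
        write_table(background, out / "background.tsv")
        truth.to_json(out / "ground_truth.json")
    else:
        breath = read_table(config.breath_path)
        background = read_table(config.background_path)

    # --- screens (group contrast on breath; site contrast on background air)
    group_screen = screen_biomarkers(breath, config.alpha_family)
    site_screen = screen_env_nondifferential(background, config.alpha_family)
    group_screen.to_frame().to_csv(out / "screen_group.tsv", sep="\t", index=False,
                                   float_format="%.10g")
    site_screen.to_frame().to_csv(out / "screen_site.tsv", sep="\t", index=False,
                                  float_format="%.10g")
    _write_json({"group": group_screen.summary(), "site": site_screen.summary()},
                out / "screen_summary.json")

    # --- clustergram bundle
    mat, rows, cols = cluster_table(breath, config.pseudocount, config.distance, config.linkage)
    gframe = group_screen.to_frame().set_index("voc_id")
    sframe = site_screen.to_frame().set_index("voc_id")
    voc_ann = pd.DataFrame({
        "significant": gframe["significant_all"],
        "env_nondifferential": sframe["nondifferential_all"],
    })
    sample_ann = breath.set_index("sample_id")[["group", "site"]]
    export_heatmap_bundle(mat, rows, cols, voc_ann, sample_ann, out / "cluster")

    # --- model variants
    split = SplitSpec(config.train_fraction, config.stratified, stage_seed(config.seed, "split"))
    smote = SmoteConfig(config.smote_k, seed=stage_seed(config.seed, "smote"))
    reports = {}
    for variant in VARIANTS:
        rep = run_variant(
            variant, breath, background=background,
            screen=site_screen if variant == "M3" else None,
            split=split, smote=smote, params=config.xgb,
            alpha_family=config.alpha_family,
            threshold=config.decision_threshold,
            full_dataset_screen=config.full_dataset_screen,
        )
        reports[variant] = rep.to_dict()
        _write_json(rep.to_dict(), out / f"model_{variant}.json")

    manifest = {
        "breathvoc_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
        "screens": {"group": group_screen.summary(), "site": site_screen.summary()},
        "models": {v: {k: reports[v][k] for k in
                       ("accuracy", "sensitivity", "specificity", "auc")}
                   for v in VARIANTS},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
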