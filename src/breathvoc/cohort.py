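"""Synthetic breath / background-air cohort generator.

The generator emulates the structure of a two-site lung-cancer breathomics
case-control study: all cancer cases sampled at the hospital site, healthy
controls split between a university campus and the hospital, plus ambient
("background-air") samples from both sites.  This site/disease entanglement
is the confounding structure the downstream environmental adjustment exists
to handle.

Generative model (log10 ppb throughout):

* background air, site s, VOC j:   10**e,  e ~ Normal(nu_{j,s}, tau_j)
  Environmentally differential VOCs have |nu_{j,campus} - nu_{j,hospital}|
  equal to ``site_shift``; all other VOCs have identical site means.
* breath, subject i, VOC j:        10**x + alpha_j * 10**e
  with endogenous x ~ Normal(mu_j + delta_j * 1[cancer], sigma_within) and an
  environmental draw e from the subject's site's background distribution.
  Mixing is additive on the concentration scale: ambient load physically adds
  to the exhaled load.
* a small set of "sparse" disease VOCs is zero-inflated in controls
  (benzoic-acid-like: near-absent in most healthy subjects).

All concentrations are floored at ``lod_floor`` except exact zeros from the
zero-inflation mechanism.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .siftms import InvalidInputError, META_COLS

GROUPS = ("cancer", "healthy")
SITES = ("campus", "hospital")
TYPES = ("breath", "background-air")


@dataclass
class SimConfig:
    # cohort structure (defaults: the study sizes)
    n_cancer: int = 148
    n_control_campus: int = 112
    n_control_hospital: int = 56
    n_bg_campus: int = 18
    n_bg_hospital: int = 29
    panel_size: int = 116
    disease_set_size: int = 50
    env_differential_set_size: int = 59
    sparse_set_size: int = 8
    # effect structure (log10 units)
    effect_size: float = 1.0
    sigma_within: float = 0.3
    site_shift: float = 1.0
    tau_background: float = 0.2
    env_coupling: float = 0.2  # alpha, shared across VOCs unless overridden
    # optional distinct coupling for env-differential VOCs (planted-confounding
    # scenarios set this to 1.0 while zeroing env_coupling)
    env_coupling_differential: float | None = None
    # floors / sparsity
    lod_floor: float = 0.01  # ppb
    zero_inflation_p: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer", "n_control_campus", "n_control_hospital",
                     "n_bg_campus", "n_bg_hospital", "panel_size"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.disease_set_size > self.panel_size:
            raise InvalidInputError("disease_set_size must be <= panel_size")
        if self.env_differential_set_size > self.panel_size:
            raise InvalidInputError("env_differential_set_size must be <= panel_size")
        if self.sparse_set_size > self.disease_set_size:
            raise InvalidInputError("sparse_set_size must be <= disease_set_size")
        if not self.sigma_within > 0:
            raise InvalidInputError("sigma_within must be > 0")
        if not (0 <= self.env_coupling <= 1):
            raise InvalidInputError("env_coupling must be in [0, 1]")
        if self.env_coupling_differential is not None and not (
            0 <= self.env_coupling_differential <= 1
        ):
            raise InvalidInputError("env_coupling_differential must be in [0, 1]")
        if not (0 <= self.zero_inflation_p <= 1):
            raise InvalidInputError("zero_inflation_p must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted generative parameters, for parameter-recovery tests."""

    voc_ids: list[str]
    disease_vocs: list[str]
    env_differential_vocs: list[str]
    sparse_vocs: list[str]
    mu: dict[str, float]                 # endogenous baseline, log10 ppb
    delta: dict[str, float]              # cancer shift; exactly 0 off the disease set
    nu_campus: dict[str, float]          # background mean per site
    nu_hospital: dict[str, float]
    tau: dict[str, float]
    alpha: dict[str, float]              # env-to-breath coupling in [0, 1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _voc_ids(m: int) -> list[str]:
    return [f"voc_{j + 1:03d}" for j in range(m)]


def draw_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Draw per-VOC generative parameters; deterministic in cfg.seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    ids = _voc_ids(cfg.panel_size)
    disease = sorted(rng.choice(ids, size=cfg.disease_set_size, replace=False).tolist())
    env_diff = sorted(rng.choice(ids, size=cfg.env_differential_set_size, replace=False).tolist())
    sparse = sorted(rng.choice(disease, size=cfg.sparse_set_size, replace=False).tolist())

    mu = dict(zip(ids, rng.uniform(0.0, 2.0, size=cfg.panel_size)))
    delta = {j: (cfg.effect_size if j in set(disease) else 0.0) for j in ids}
    nu_c = dict(zip(ids, rng.uniform(-1.0, 1.0, size=cfg.panel_size)))
    signs = dict(zip(ids, rng.choice([-1.0, 1.0], size=cfg.panel_size)))
    nu_h = {
        j: (nu_c[j] + signs[j] * cfg.site_shift if j in set(env_diff) else nu_c[j])
        for j in ids
    }
    tau = {j: cfg.tau_background for j in ids}
    alpha_diff = (cfg.env_coupling if cfg.env_coupling_differential is None
                  else cfg.env_coupling_differential)
    alpha = {j: (alpha_diff if j in set(env_diff) else cfg.env_coupling) for j in ids}
    return GroundTruth(ids, disease, env_diff, sparse, mu, delta, nu_c, nu_h, tau, alpha)


def _background_mean(truth: GroundTruth, voc: str, site: str) -> float:
    return truth.nu_campus[voc] if site == "campus" else truth.nu_hospital[voc]


def simulate_background(cfg: SimConfig, truth: GroundTruth | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Ambient-air sample table for both sites."""
    if truth is None:
        truth = draw_ground_truth(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    sites = ["campus"] * cfg.n_bg_campus + ["hospital"] * cfg.n_bg_hospital
    n = len(sites)
    m = cfg.panel_size
    nu = np.array([[_background_mean(truth, j, s) for j in truth.voc_ids] for s in sites])
    tau = np.array([truth.tau[j] for j in truth.voc_ids])
    conc = np.power(10.0, rng.normal(nu, tau[None, :], size=(n, m)))
    conc = np.maximum(conc, cfg.lod_floor)
    df = pd.DataFrame(conc, columns=truth.voc_ids)
    df.insert(0, "sample_id", [f"BG{i + 1:04d}" for i in range(n)])
    df.insert(1, "subject_id", [f"env_{i + 1:04d}" for i in range(n)])
    df.insert(2, "group", "none")
    df.insert(3, "site", sites)
    df.insert(4, "type", "background-air")
    return df, truth


def simulate_cohort(
    cfg: SimConfig,
    background: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Breath sample table: cases (hospital) and site-split controls.

    ``background`` must cover both sites; its generative distribution (via the
    shared ground truth) supplies each subject's environmental draw.
    """
    if truth is None:
        truth = draw_ground_truth(cfg)
    present = set(background["site"].unique())
    missing = set(SITES) - present
    if missing:
        raise InvalidInputError(f"background table missing site(s): {sorted(missing)}")

    rng = np.random.default_rng([cfg.seed, 2])
    groups = (["cancer"] * cfg.n_cancer
              + ["healthy"] * (cfg.n_control_campus + cfg.n_control_hospital))
    sites = (["hospital"] * cfg.n_cancer
             + ["campus"] * cfg.n_control_campus
             + ["hospital"] * cfg.n_control_hospital)
    n, m = len(groups), cfg.panel_size
    ids = truth.voc_ids

    mu = np.array([truth.mu[j] for j in ids])
    delta = np.array([truth.delta[j] for j in ids])
    alpha = np.array([truth.alpha[j] for j in ids])
    tau = np.array([truth.tau[j] for j in ids])
    is_cancer = np.array([g == "cancer" for g in groups], dtype=float)
    nu = np.array([[_background_mean(truth, j, s) for j in ids] for s in sites])

    x = rng.normal(mu[None, :] + np.outer(is_cancer, delta), cfg.sigma_within, size=(n, m))
    e = rng.normal(nu, tau[None, :], size=(n, m))
    conc = np.power(10.0, x) + alpha[None, :] * np.power(10.0, e)
    conc = np.maximum(conc, cfg.lod_floor)

    # zero inflation: sparse disease VOCs are below detection in most controls
    sparse_idx = [ids.index(j) for j in truth.sparse_vocs]
    control_rows = np.where(is_cancer == 0)[0]
    for jx in sparse_idx:
        off = rng.random(len(control_rows)) < cfg.zero_inflation_p
        conc[control_rows[off], jx] = 0.0

    df = pd.DataFrame(conc, columns=ids)
    df.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(n)])
    df.insert(1, "subject_id", [f"subj_{i + 1:04d}" for i in range(n)])
    df.insert(2, "group", groups)
    df.insert(3, "site", sites)
    df.insert(4, "type", "breath")
    return df, truth


def simulate_study(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: (breath table, background table, ground truth)."""
    truth = draw_ground_truth(cfg)
    background, _ = simulate_background(cfg, truth)
    breath, _ = simulate_cohort(cfg, background, truth)
    return breath, background, truth


def voc_columns(table: pd.DataFrame) -> list[str]:
    """The VOC feature columns of a wide sample table."""
    return [c for c in table.columns if c not in META_COLS]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
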