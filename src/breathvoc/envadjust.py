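"""Environmental-VOC adjustment: SMOTE-style synthesis and panel restriction.

Breath VOC levels mix endogenous production with ambient air, and when cases
and controls are sampled at different sites the ambient component confounds
the disease signal.  Two adjustments are provided:

1. ``assign_environment`` synthesizes one ambient VOC vector per participant
   from the background-air samples collected at that participant's site,
   using the SMOTE interpolation rule, and appends it to the breath features
   so the classifier can learn the environmental contribution explicitly.
2. ``restrict_to_nondifferential`` simply drops every VOC whose ambient level
   differs between sites, keeping only environmentally nondifferential VOCs.

The SMOTE rule (implemented here from first principles): pick a donor x
uniformly, pick z uniformly among x's k nearest neighbors (Euclidean), draw
u ~ Uniform(0,1) once, and return s = x + u * (z - x).  Every synthetic
coordinate therefore lies within the [min, max] envelope of its donor pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import voc_columns
from .siftms import InvalidInputError, SchemaError


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    distance_space: str = "raw"  # "raw" | "log"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise InvalidInputError("k_neighbors must be >= 1")
        if self.distance_space not in ("raw", "log"):
            raise InvalidInputError("distance_space must be 'raw' or 'log'")


def smote_synthesize(
    donors: np.ndarray | pd.DataFrame,
    n_out: int,
    cfg: SmoteConfig,
    u_override: float | None = None,
) -> np.ndarray:
    """Synthesize ``n_out`` vectors by SMOTE interpolation among ``donors``.

    ``u_override`` pins the interpolation weight (test hook; u=0 returns the
    donor itself).  Deterministic under cfg.seed.
    """
    x = np.asarray(donors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidInputError("need >= 2 donor samples")
    n_donors = x.shape[0]
    k = cfg.k_neighbors
    if k >= n_donors:
        raise InvalidInputError(f"k_neighbors ({k}) must be < number of donors ({n_donors})")

    space = np.log10(x + 1e-3) if cfg.distance_space == "log" else x
    d = np.linalg.norm(space[:, None, :] - space[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    # k nearest neighbors of each donor; stable argsort keeps ties by index
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_donors, size=n_out)
    pick = rng.integers(0, k, size=n_out)
    u = rng.random(n_out) if u_override is None else np.full(n_out, float(u_override))
    neighbor = nn[base, pick]
    return x[base] + u[:, None] * (x[neighbor] - x[base])


def assign_environment(
    participants: pd.DataFrame,
    background: pd.DataFrame,
    cfg: SmoteConfig,
) -> pd.DataFrame:
    """One synthetic site-matched environment vector per participant.

    Returns the augmented table: metadata, breath block (``voc_*`` columns as
    given) and environment block (``env_*`` columns).  k is capped at
    n_donors - 1 per site so the canonical k=5 works with small donor pools.
    """
    vocs = voc_columns(participants)
    bg_vocs = voc_columns(background)
    if vocs != bg_vocs:
        raise SchemaError("participant and background tables must share the VOC panel")

    out = participants.copy()
    env = np.empty((len(participants), len(vocs)))
    for site, idx in participants.groupby("site").indices.items():
        donors = background.loc[background["site"] == site, vocs]
        if len(donors) < 2:
            raise InvalidInputError(f"site {site!r} has < 2 background donor samples")
        k = min(cfg.k_neighbors, len(donors) - 1)
        site_cfg = SmoteConfig(k, cfg.distance_space, cfg.seed)
        env[idx] = smote_synthesize(donors, len(idx), site_cfg)
    env_df = pd.DataFrame(env, columns=[f"env_{v}" for v in vocs], index=participants.index)
    return pd.concat([out, env_df], axis=1)


def restrict_to_nondifferential(table: pd.DataFrame, keep: set[str] | list[str]) -> pd.DataFrame:
    """Project the table onto the ``keep`` VOC subset; metadata untouched."""
    keep = list(keep)
    if not keep:
        raise InvalidInputError("keep set must be non-empty")
    panel = set(voc_columns(table))
    unknown = sorted(set(keep) - panel)
    if unknown:
        raise SchemaError(f"unknown VOC ids in keep set: {unknown}")
    meta = [c for c in table.columns if c not in panel]
    ordered = [v for v in voc_columns(table) if v in set(keep)]
    return table[meta + ordered]
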