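"""Train/test splitting, gradient-boosted classification, and metrics.

The disease-state classifier is a gradient-boosted tree ensemble (XGBoost)
scored on a held-out test fraction.  Four feature constructions are compared:

* M1 — all panel VOCs;
* M2 — only VOCs flagged as biomarkers by the triple-test screen;
* M3 — only environmentally nondifferential VOCs (ambient levels equal
  across sites), the drop-the-confounded-features adjustment;
* M4 — all VOCs plus a synthetic site-matched environment vector per
  participant (SMOTE over background-air donors), the model-the-confounder
  adjustment.

Cancer is the positive class throughout.  AUC is computed by the rank
(Mann-Whitney) formula with half-credit for ties, which equals trapezoidal
integration of the ROC curve.  By default the M2/M3 screens run on the
training fold only to avoid selection leakage; ``full_dataset_screen=True``
screens on the full table instead (full-dataset selection before splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .cohort import voc_columns
from .envadjust import SmoteConfig, assign_environment, restrict_to_nondifferential
from .screen import screen_biomarkers, screen_env_nondifferential, ScreenResult
from .siftms import InvalidInputError

VARIANTS = ("M1", "M2", "M3", "M4")


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise InvalidInputError("train_fraction must be in (0, 1)")


@dataclass
class XgbParams:
    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1


@dataclass
class ModelEvalReport:
    variant: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_train: int
    n_test: int
    seed: int
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def split_data(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, stratified by group."""
    counts = table["group"].value_counts()
    if len(counts) < 2:
        raise InvalidInputError("both classes must be present")
    if (counts < 2).any():
        raise InvalidInputError("each class needs >= 2 samples")
    strat = table["group"] if spec.stratified else None
    train, test = train_test_split(
        table, train_size=spec.train_fraction, stratify=strat, random_state=spec.seed
    )
    return train, test


def train_model(
    features: pd.DataFrame,
    labels: Sequence[int],
    params: XgbParams | None = None,
    seed: int = 0,
) -> XGBClassifier:
    """Fit a gradient-boosted tree classifier; reproducible under seed."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training labels contain a single class")
    params = params or XgbParams()
    clf = XGBClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        tree_method="hist",
    )
    clf.fit(features.to_numpy(dtype=float), y)
    return clf


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic, ties half-credited.

    Equals P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg), i.e.
    trapezoidal ROC integration.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("labels must contain both classes")
    ranks = stats.rankdata(s)  # mid-ranks handle ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    variant: str = "",
    n_train: int = 0,
    seed: int = 0,
    features: Sequence[str] = (),
) -> ModelEvalReport:
    """Confusion metrics at ``threshold`` plus rank-formula AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(s) != len(y):
        raise InvalidInputError("scores and labels must align")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    auc = rank_auc(s, y)
    return ModelEvalReport(
        variant=variant, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc, n_train=n_train, n_test=len(y), seed=seed,
        features=list(features),
    )


def _labels(table: pd.DataFrame) -> np.ndarray:
    return (table["group"] == "cancer").to_numpy(dtype=int)


def run_variant(
    variant: str,
    breath: pd.DataFrame,
    background: pd.DataFrame | None = None,
    screen: ScreenResult | None = None,
    split: SplitSpec | None = None,
    smote: SmoteConfig | None = None,
    params: XgbParams | None = None,
    alpha_family: float = 0.05,
    threshold: float = 0.5,
    full_dataset_screen: bool = False,
) -> ModelEvalReport:
    """Run one model variant end to end: features -> split -> train -> evaluate.

    M2 screens biomarkers on the training fold (or the full table under
    ``full_dataset_screen``) unless a pre-computed ``screen`` is supplied.  M3
    requires a background table (or a pre-computed site screen); M4 requires
    a background table.
    """
    if variant not in VARIANTS:
        raise InvalidInputError(f"variant must be one of {VARIANTS}")
    split = split or SplitSpec()
    smote = smote or SmoteConfig(seed=split.seed)

    table = breath
    if variant == "M4":
        if background is None:
            raise InvalidInputError("M4 requires a background table")
        table = assign_environment(breath, background, smote)

    train, test = split_data(table, split)

    if variant == "M1" or variant == "M4":
        feats = voc_columns(table)
    elif variant == "M2":
        scr = screen or screen_biomarkers(breath if full_dataset_screen else train, alpha_family)
        feats = sorted(scr.biomarker_set)
        if not feats:
            raise InvalidInputError("M2: biomarker set is empty")
    else:  # M3
        if screen is not None:
            scr = screen
        elif background is not None:
            scr = screen_env_nondifferential(background, alpha_family)
        else:
            raise InvalidInputError("M3 requires a background table or a site screen")
        feats = sorted(scr.nondifferential_set)
        if not feats:
            raise InvalidInputError("M3: nondifferential set is empty")

    clf = train_model(train[feats], _labels(train), params, seed=split.seed)
    scores = clf.predict_proba(test[feats].to_numpy(dtype=float))[:, 1]
    return evaluate(scores, _labels(test), threshold, variant,
                    n_train=len(train), seed=split.seed, features=feats)


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for export."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # collapse ties: keep the last point of each distinct score
    keep = np.r_[np.diff(s) != 0, True]
    df = pd.DataFrame({
        "threshold": s[keep],
        "tpr": tps[keep] / max(n_pos, 1),
        "fpr": fps[keep] / max(n_neg, 1),
    })
    return pd.concat([pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}), df],
                     ignore_index=True)
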