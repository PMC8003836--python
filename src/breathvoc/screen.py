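"""Per-VOC hypothesis testing and the triple-test consensus screens.

Each VOC is tested for a group difference with three two-sided tests: the
Wilcoxon rank-sum (Mann-Whitney) test, the pooled-variance two-sample t-test,
and the Welch t-test.  Significance is assessed against a Bonferroni-corrected
family threshold alpha/m where m is the full panel size.  A VOC is called a
biomarker when all three p-values fall below the threshold (cancer vs control
contrast on breath samples); it is called environmentally nondifferential when
all three p-values are at or above the threshold (campus vs hospital contrast
on background-air samples).  The consensus-of-three is at least as
conservative as any single Bonferroni-corrected test, so family-wise error is
controlled at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import voc_columns
from .siftms import InvalidInputError


@dataclass
class TestTriplet:
    voc_id: str
    p_wilcoxon: float
    p_student: float
    p_welch: float
    mean_log_a: float
    mean_log_b: float
    n_a: int
    n_b: int
    testable: bool = True

    def all_below(self, threshold: float) -> bool:
        return (self.testable
                and self.p_wilcoxon < threshold
                and self.p_student < threshold
                and self.p_welch < threshold)

    def all_at_or_above(self, threshold: float) -> bool:
        return (self.testable
                and self.p_wilcoxon >= threshold
                and self.p_student >= threshold
                and self.p_welch >= threshold)


@dataclass
class ScreenResult:
    triplets: list[TestTriplet]
    alpha_family: float
    m_tests: int
    contrast: str  # "group" or "site"

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha_family, self.m_tests)

    @property
    def biomarker_set(self) -> set[str]:
        return {t.voc_id for t in self.triplets if t.all_below(self.threshold)}

    @property
    def nondifferential_set(self) -> set[str]:
        return {t.voc_id for t in self.triplets if t.all_at_or_above(self.threshold)}

    def to_frame(self) -> pd.DataFrame:
        thr = self.threshold
        return pd.DataFrame(
            {
                "voc_id": [t.voc_id for t in self.triplets],
                "p_wilcoxon": [t.p_wilcoxon for t in self.triplets],
                "p_student": [t.p_student for t in self.triplets],
                "p_welch": [t.p_welch for t in self.triplets],
                "mean_log_a": [t.mean_log_a for t in self.triplets],
                "mean_log_b": [t.mean_log_b for t in self.triplets],
                "n_a": [t.n_a for t in self.triplets],
                "n_b": [t.n_b for t in self.triplets],
                "testable": [t.testable for t in self.triplets],
                "significant_all": [t.all_below(thr) for t in self.triplets],
                "nondifferential_all": [t.all_at_or_above(thr) for t in self.triplets],
            }
        )

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "alpha_family": self.alpha_family,
            "m_tests": self.m_tests,
            "threshold": self.threshold,
            "n_biomarkers": len(self.biomarker_set),
            "n_nondifferential": len(self.nondifferential_set),
        }


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Family threshold alpha/m (e.g. 0.05/116 ~ 4.31e-4)."""
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    if not (0 < alpha_family < 1):
        raise InvalidInputError("alpha_family must be in (0, 1)")
    return alpha_family / m


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact null distribution when feasible (small groups, no ties), normal
    # approximation with mid-rank tie correction otherwise
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def triple_test(values_a: Sequence[float], values_b: Sequence[float], voc_id: str = "") -> TestTriplet:
    """Wilcoxon rank-sum + pooled t + Welch t, all two-sided.

    Degenerate inputs with zero variance in both groups and equal means give
    p = 1 for the t-tests (no evidence) instead of NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs >= 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidInputError("values must be finite")

    p_w = _wilcoxon_p(a, b)
    degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
    if degenerate:
        p_s = p_t = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p_s = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        p_t = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    with np.errstate(divide="ignore"):
        ml_a = float(np.log10(a[a > 0]).mean()) if (a > 0).any() else float("nan")
        ml_b = float(np.log10(b[b > 0]).mean()) if (b > 0).any() else float("nan")
    return TestTriplet(voc_id, p_w, p_s, p_t, ml_a, ml_b, len(a), len(b))


def _screen(
    table: pd.DataFrame,
    label_col: str,
    level_a: str,
    level_b: str,
    alpha_family: float,
    contrast: str,
) -> ScreenResult:
    vocs = voc_columns(table)
    mask_a = table[label_col] == level_a
    mask_b = table[label_col] == level_b
    if not mask_a.any() or not mask_b.any():
        raise InvalidInputError(f"both {label_col} levels ({level_a}, {level_b}) must be present")
    triplets = []
    for j in vocs:
        a = table.loc[mask_a, j].dropna().to_numpy(dtype=float)
        b = table.loc[mask_b, j].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            # untestable: reported, excluded from both consensus sets, but the
            # Bonferroni divisor stays the full panel size
            triplets.append(TestTriplet(j, np.nan, np.nan, np.nan, np.nan, np.nan,
                                        len(a), len(b), testable=False))
            continue
        triplets.append(triple_test(a, b, voc_id=j))
    return ScreenResult(triplets, alpha_family, len(vocs), contrast)


def screen_biomarkers(table: pd.DataFrame, alpha_family: float = 0.05) -> ScreenResult:
    """Cancer-vs-healthy screen over the breath rows of ``table``."""
    breath = table[table["type"] == "breath"] if "type" in table.columns else table
    return _screen(breath, "group", "cancer", "healthy", alpha_family, "group")


def screen_env_nondifferential(table: pd.DataFrame, alpha_family: float = 0.05) -> ScreenResult:
    """Campus-vs-hospital screen over the background-air rows of ``table``."""
    bg = table[table["type"] == "background-air"] if "type" in table.columns else table
    return _screen(bg, "site", "campus", "hospital", alpha_family, "site")


# ---------------------------------------------------------------------------
# cohort characteristics table


def format_count_pct(count: int, total: int) -> str:
    """'65 of 148' -> '65 (43.9)'."""
    return f"{count} ({100.0 * count / total:.1f})"


def _normality_implausible(x: np.ndarray, alpha: float = 0.01) -> bool:
    if len(x) < 8 or np.var(x) == 0:
        return False
    return stats.shapiro(x).pvalue < alpha


def cohort_table(
    metadata: pd.DataFrame,
    group_col: str,
    continuous_vars: Sequence[str] = (),
    categorical_vars: Sequence[str] = (),
    normality_rule: Callable[[np.ndarray], bool] | None = None,
) -> pd.DataFrame:
    """Per-variable group comparisons for a cohort-characteristics table.

    Continuous variables: two-sample t-test, falling back to the Wilcoxon
    rank-sum test when ``normality_rule`` deems normality implausible in
    either group (default: Shapiro-Wilk p < 0.01).  Categorical variables:
    chi-square, or Fisher's exact test for 2x2 tables with any expected cell
    below 5.  Summaries: mean +/- SD for continuous, "n (%)" per level for
    categorical.
    """
    rule = normality_rule or _normality_implausible
    levels = [lv for lv in metadata[group_col].unique() if pd.notna(lv)]
    if len(levels) != 2:
        raise InvalidInputError("cohort_table expects exactly 2 groups")
    ga, gb = levels
    rows = []
    for var in continuous_vars:
        a = metadata.loc[metadata[group_col] == ga, var].dropna().to_numpy(dtype=float)
        b = metadata.loc[metadata[group_col] == gb, var].dropna().to_numpy(dtype=float)
        if rule(a) or rule(b):
            test, p = "wilcoxon", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            test, p = "t-test", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({
            "variable": var, "level": "",
            "summary_a": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
            "summary_b": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
            "test": test, "p_value": p,
        })
    for var in categorical_vars:
        sub = metadata[[group_col, var]].dropna()
        ct = pd.crosstab(sub[var], sub[group_col])
        ct = ct.loc[(ct.sum(axis=1) > 0)]
        if ct.shape[0] < 2:
            continue  # a single observed level carries no contrast
        observed = ct[[ga, gb]].to_numpy()
        expected = stats.contingency.expected_freq(observed)
        # Cochran-style adequacy: the chi-square approximation needs expected
        # counts comfortably above 5, so a 2x2 with any expected cell at or
        # below 5 goes to the exact test
        if observed.shape == (2, 2) and (expected <= 5).any():
            test, p = "fisher", float(stats.fisher_exact(observed).pvalue)
        else:
            test, p = "chi-square", float(stats.chi2_contingency(observed).pvalue)
        tot_a, tot_b = int(ct[ga].sum()), int(ct[gb].sum())
        for level in ct.index:
            rows.append({
                "variable": var, "level": str(level),
                "summary_a": format_count_pct(int(ct.loc[level, ga]), tot_a),
                "summary_b": format_count_pct(int(ct.loc[level, gb]), tot_b),
                "test": test, "p_value": p,
            })
    return pd.DataFrame(rows)
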