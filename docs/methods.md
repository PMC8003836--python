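# Methods

## SIFT-MS quantification

Selected-ion-mode SIFT-MS counts precursor (reagent) ions and the
characteristic product ions of each analyte. Under first-order kinetics the
analyte number density is

    [A] = R_product / (R_precursor · k_eff · t_reaction),   k_eff = k · b,

with rate coefficient k (cm³·s⁻¹), branching fraction b ∈ (0,1], and flow-tube
reaction time t (s). Division by the carrier-gas number density (default
2.46×10¹⁹ cm⁻³, 1 atm / 298 K) and scaling by 10⁹ gives ppb by volume. The
conversion is linear in the product count rate and inversely linear in the
precursor rate; both properties are enforced by tests. Instrument constants
are not universal, so they live in `InstrumentParams` (reaction_time 5 ms,
dilution 1, configurable).

**Tolerance consensus.** Each compound is monitored on ≥1 channels; isobaric
interference inflates shared channels. With per-channel estimates c₁…cₙ and
tolerance f = 0.20, the accepted set is {c : c ≤ (1+f)·min c} — boundary
*inclusive*, a choice we fixed because "within 20%" is ambiguous — and the
consensus is the unweighted mean of the accepted set. The minimum is always
accepted, so the consensus lies in [min c, 1.2·min c]. A compound whose every
channel is interfered cannot be absolutely quantified and carries a
`relative` scale flag through the table unchanged in units.

Missing channels are *dropped* from the consensus, never treated as zero: a
zero would always capture the minimum and drag the consensus to zero. A
sample with no scans for a compound reports NA, not 0.

**Stability QC.** Repeated measurements per VOC give CV = sd/mean (sample sd,
n−1), defined 0 when both are 0; a VOC is stable iff CV ≤ threshold
(default 0.2).

The shipped compound panel (`placeholder_library`) is illustrative plumbing
for tests and demos; real analyses supply their instrument's method file as
the library CSV.

## Synthetic cohort generator

The generator emulates a two-site case-control breathomics study in which
disease status and sampling site are entangled: all 148 cancer cases at the
hospital, 112 of 168 controls at a campus, plus 18 campus / 29 hospital
background-air samples. Defaults mirror those counts and a 116-VOC panel
with 50 disease-associated and 59 site-differential ambient VOCs.

Per VOC j (log10 ppb):

- background air at site s: e ~ N(ν_js, τ_j); site-differential VOCs have
  |ν_j,campus − ν_j,hospital| = `site_shift` (default 1.0), others 0.
  Baselines ν ~ U(−1, 1), τ = 0.2.
- breath of subject i: endogenous x ~ N(μ_j + δ_j·1[cancer], σ) with
  μ ~ U(0, 2), σ = 0.3, δ = `effect_size` (default 1.0) on the disease set
  and exactly 0 elsewhere; observed concentration 10^x + α_j·10^e with the
  environmental draw e taken from the subject's site's background
  distribution. Mixing is additive on the *concentration* scale because
  ambient load physically adds to the exhaled load; α_j ∈ [0,1] is the
  coupling (default 0.2 everywhere; confounding experiments set α = 1 on the
  site-differential set and 0 elsewhere via `env_coupling_differential`).
- a small "sparse" subset of disease VOCs (8 by default) is zero-inflated in
  controls (p = 0.3), mimicking compounds nearly absent in healthy breath.

All cells are floored at the detection limit (0.01 ppb) except exact
zero-inflation zeros. Log-normal within-group distributions reflect that
concentrations are positive and right-skewed and that the exploratory
analysis works on log concentrations. Defaults for δ, σ, and the shifts are
chosen for testability: δ/σ ≈ 3.3 makes per-VOC power ≈ 1 at n = 148/168, so
recovery failures indicate implementation defects rather than sampling noise.

What the generator does *not* emulate: age/smoking/diet covariates (the
study measured but did not adjust for them), longitudinal or repeated
sampling, inter-VOC correlation beyond the shared site environment, and raw
ion-scan level noise (a separate fixture generator covers quantification).
Passing tests therefore demonstrate pipeline correctness under the stated
generative model, not clinical performance on real cohorts.

## Screening

Each VOC is tested cancer-vs-healthy (breath) or campus-vs-hospital
(background air) with three two-sided tests: Wilcoxon rank-sum — exact null
distribution when min(n) ≤ 8 and there are no ties, normal approximation
with mid-rank tie correction otherwise — plus pooled-variance and Welch
t-tests. Zero-variance equal-mean degenerates return p = 1 so constant
columns never error. Missing values are handled pairwise-complete per VOC; a
VOC with fewer than two complete observations in a group is reported
untestable and excluded from both consensus sets, but the Bonferroni divisor
stays the full panel size m (the printed threshold is 0.05/116 regardless of
testability). A biomarker needs p < α/m in *all three* tests; an
environmentally nondifferential VOC needs p ≥ α/m in all three. The
consensus-of-three is at least as conservative as any single
Bonferroni-corrected test, giving family-wise error ≤ α under the global
null (verified by simulation over 200 null cohorts).

Cohort-characteristics tables use Welch's t for continuous variables with a
Wilcoxon fallback when Shapiro-Wilk (p < 0.01 in either group) makes
normality implausible, and chi-square for categorical variables with
Fisher's exact test for 2×2 tables whose expected counts reach 5 or below
(the Cochran adequacy region, where the χ² approximation is unreliable).
Percentages print as "n (pct)" with one decimal.

## Clustering

Samples and VOCs are clustered agglomeratively on log10(x + 0.001)
concentrations with Euclidean distance and complete linkage; metric,
linkage, log base and pseudocount are package choices, all configurable,
since no single convention dominates for clustergrams of breath VOC panels. Missing cells are imputed with the per-VOC minimum observed value
first — below-LOD semantics. Complete linkage guarantees non-decreasing
merge heights; heights are verified against a brute-force agglomerator on
small matrices. Tie-breaking among equal-height merges follows
scipy.cluster.hierarchy's deterministic order, so repeated runs are
identical. The export is a plotting-agnostic bundle: reordered matrix (TSV),
merge trees (JSON), annotation tracks (TSV).

## Environmental adjustment

SMOTE is implemented from first principles because it is used here
*generatively*, not for class imbalance: each site's background-air samples
form a donor pool, and every participant receives one synthetic ambient
vector from their own site's pool — the only reading consistent with
site-specific backgrounds and per-participant synthesis. One interpolation
weight u ~ U(0,1) is shared across coordinates (classical SMOTE), so every
synthetic coordinate lies in the donor pair's [min, max] envelope; k = 5
neighbours by default, capped at n_donors − 1 (17 campus / 28 hospital at
study scale). Neighbours are found in raw concentration space by default
(log space via config). The alternative adjustment simply restricts the
panel to environmentally nondifferential VOCs.

## Classification and evaluation

XGBoost with 200 trees, depth 4, learning rate 0.1 — conservative defaults
for a few hundred samples and ~100–250 features, configurable — and
single-threaded for bit reproducibility. Splits are stratified 70/30 by
default. Cancer is the positive class; confusion metrics use a 0.5 score
threshold. AUC uses the Mann-Whitney rank formula with mid-ranks
(ties half-credited), proven equal to trapezoidal ROC integration by an
oracle test on random vectors.

Feature selection for M2 runs on the training fold only by default;
`full_dataset_screen=True` screens on the full table before the split, a
common but leakage-prone study design kept available for comparison —
correctness by default, fidelity on demand. M3's site screen uses background-air samples
only, which are disjoint from the classified breath samples, so it carries
no leakage either way.

## Numerical and reproducibility choices

- Stage sub-seeds derive from the global seed by a fixed counter scheme
  (seed × 1000 + stage offset, mod 2³¹), so an isolated stage re-run matches
  its in-pipeline output; `run_all` twice under one config is byte-identical
  (tested).
- Tables are TSV with 10-significant-digit floats, NA for missing; reports
  are JSON with sorted keys.
- Problem sizes in the automated checks: 10⁴ random vectors for the
  consensus oracle, 10³ for the AUC oracle, 200 replicates for the
  family-wise error simulation, 20 seeds for the confounding comparison —
  sizes at which the binomial/Monte-Carlo error of each check is well below
  its decision margin.

## Known limitations

- The model-variant metrics saturate (AUC ≈ 1) at the default planted effect
  size; the generator is a correctness harness, not a difficulty benchmark,
  and synthetic performance says nothing about real-cohort performance.
- The 116-compound panel shipped for demos is a placeholder; category
  labels, channels and rate coefficients are illustrative.
- No humidity/hydrate-cluster corrections, no full-scan mode, no covariate
  adjustment, no FDR alternative to Bonferroni.
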