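# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Data model

The unit of analysis is a subjects × variables matrix of gated cytometry
population frequencies in percent-of-parent units. Frequencies are
non-negative, right-skewed, and missing preferentially in low-frequency
populations (a sparse parent gate leaves too few events to quantify its
children). Subject metadata carry the case/control label, age, sex, a
symmetric spousal link (spouses are always in opposite groups), an ordered
MMSE cognition band for patients (25–30, 20–24, 10–19, <10), APOE ε4
carrier status, EBV/CMV serostatus booleans (thresholds applied upstream),
and optional fluid biomarkers.

## Preprocessing

**Missingness filter.** A variable is kept iff its missing fraction is
≤ the threshold (default 0.20); the boundary is inclusive (strictly
greater is dropped). Subjects are never dropped at this stage. The filter
runs on the full subject set, before any subject-level exclusion.

**Box–Cox.** Per variable, λ maximizes the Box–Cox profile log-likelihood
(scipy's `boxcox_llf` under a bounded scalar optimizer), clamped to
[−5, 5]. The positivity shift is `1 − min(x)` when `min(x) ≤ 0`, else 0 —
the only convention that guarantees strict positivity for frequency data
that can be exactly zero. λ = 0 means a natural log. Zero-variance input
returns λ = 1 with a warning; the transform chain drops such variables
since they cannot be standardized. Transform parameters (λ, shift, mean,
SD per variable) are fitted once on all subjects pooled — cases and
controls together — and stored in a `TransformSpec` (JSON) so the
identical mapping can be applied to new subjects.

**Standardization.** Sample z-score (ddof = 1) over observed entries;
missing stays missing.

**kNN imputation.** Distance between subjects is the Euclidean distance
over variables observed in both, rescaled by √(p / p_shared) (partial-
distance convention; `nan_euclidean_distances`). Each missing cell takes
the median (configurable to mean) of that variable among the k = 3 nearest
donors observing it; fewer available donors are used with a warning; ties
in donor distance break by subject order so imputation is deterministic.
The function refuses raw-percent input (crude mean/SD check) because
unstandardized columns would dominate the distance.

Because every step is a monotone per-variable map, observed cells keep
their within-variable ranks through the whole chain — asserted as a
property test.

## Association scan

Per variable: `Logit(disease ~ variable + age + sexM)` by maximum
likelihood; OR = exp(β_variable) with Wald 95 % CI and p. Wald (not
profile) intervals match standard OR reporting. Sex is a single indicator
with reference F (alphabetical, deterministic; the variable's coefficient
is invariant to the reference). Perfect/quasi-separation and
non-convergence flag the record unusable — estimate set missing — rather
than reporting |β| in the tens. Age-association models are OLS of the
standardized variable on z-scored age + sex, fit inside each group (HC,
AD) or overall. BH-adjusted p's are computed across the scan and reported
next to raw p; the ranking that feeds model building uses raw p
(ties: larger |log OR| first, then name; flagged records last).

## Incremental ridge-logistic CV

For N = 1…`max_features`, a logistic model with an L2 penalty (fixed
λ_ridge = 1.0 on the standardized candidate variables; the paper-style
protocol does not specify a strength, and a single fixed value keeps the
N-sweep interpretable) is fitted on the top-N variables; age and sex enter
unpenalized — they are adjustments, not candidate markers. Optimization is
L-BFGS on the exact penalized negative log-likelihood with analytic
gradient. Performance is stratified k-fold (default 10) CV AUC, where AUC
is the Mann–Whitney concordance probability (ties count ½). The fold
split is fixed per seed and shared across N so curve points are
comparable. The optimal N is the smallest argmax of the mean AUC. The
mean-AUC CI is a t-interval across folds; the averaged ROC interpolates
per-fold ROCs on a fixed 101-point FPR grid with a normal-approximation
band (± 1.96 · SD/√k).

**Ranking leakage.** Ranking candidates on the full data and then
cross-validating (the literal protocol, and the default) leaks selection
optimism: null variables with chance association keep adding held-out AUC,
so the curve flattens upward instead of declining past the informative
set. `nested_ranking=True` re-ranks inside each training fold (one
univariate scan per fold) and restores the honest peak-then-decline shape;
the synthetic benchmark uses this mode for peak-location checks.
Preprocessing statistics (transform parameters, imputation donors) are
frozen before CV in both modes — a known simplification.

## Random forest

Depth is the one constrained hyperparameter. Within each of k stratified
folds, forests (default 500 trees) are fitted at every depth in
{2, 3, 4, 5, 7, 10, unbounded} on the training part; the per-fold best
depth maximizes OOB accuracy (smallest depth on ties), and the final depth
is the mode of per-fold choices (smallest on multimodality). A full-data
forest at that depth yields Gini impurity-decrease importances, normalized
to sum 1 (descending order, name tie-break). Incremental top-N forests
give a CV-AUC curve on the same `CvCurve` type. All runs are seed-
deterministic. Correlated duplicates split importance between themselves
(masking) while their combined importance is preserved — documented and
tested rather than "fixed".

## Similarity embedding

PCA of the column-centered standardized matrix via SVD. For Euclidean
distances, classical MDS (PCoA) of the distance matrix equals PCA scores
up to component sign — asserted against an independent PCoA implementation
on random matrices to 1e-8 — so "PCA on Euclidean distances" and "PCA on
the data" are the same computation here. Signs follow a deterministic
convention (largest-|loading| variable positive per component). Biplot
arrows are loadings × scale on the PC1/PC2 plane. Group separation per
component is the absolute standardized mean difference; the summary
statistic is the Euclidean norm over the first two components (invariant
to sign flips).

## Spousal shared-environment analysis

The question: do disease-associated variables carry a cohabitation
signature, or is their shift disease-intrinsic? Actual spousal pairs are
compared with simulated re-pairings of the same subjects that preserve

* the multiset of pair sex compositions, and
* the within-pair age-gap distribution: target gaps are a random
  permutation of the actual gaps (per sex-composition class) and each
  pair is matched to the candidate realizing its target best, choosing
  uniformly among all candidates within `age_bin_width`/10 years of the
  best match. The coarseness knob trades gap fidelity against dispersion
  of the simulated sets; a near-deterministic matcher would concentrate
  the null.

Simulated sets avoid reproducing an actual pair when an alternative
exists (logged when unavoidable) and never reuse a subject within a set.

Per-pair Euclidean distance over the selected variables is the test
statistic. The permutation p is (1 + #{simulated sets with median ≤
actual median}) / (1 + n_sets): the add-one term stands in for the
identity permutation the simulator excludes, the standard finite-sample
correction that keeps the test valid at any n_sets. A two-sided
Mann–Whitney U of actual vs pooled simulated distances is reported
alongside. Calibration on null cohorts (no shared environment): measured
type-I rate 0.045 at nominal 0.05 over 200 runs; power 20/20 at ρ = 0.6
with 150 pairs (recomputed by `scripts/acceptance.py`).

**Concordance scatter.** Per variable, p_actual is the Spearman p between
partner values across actual pairs, with partner order randomized once per
pair (seeded) to avoid artefactual ordering effects; p_simulated is the
geometric mean of the same statistic over simulated sets (the
back-transform of the mean Fisher −2 ln p). Points above the identity line
on −log10 axes indicate concordance specific to the true pairing, i.e. a
shared-environment component; concordance driven by the preserved age/sex
structure appears equally on both axes and sits on the line. A
least-squares regression of −log10 p_actual on −log10 p_simulated is
reported against the identity (null) line.

## Clinical-structure tests

* Mann–Whitney U: exact p when combined n ≤ 12 without ties, otherwise
  normal approximation with tie correction.
* BH adjustment is applied strictly within one analysis family per call
  (one figure-panel's worth of comparisons), never pooled across families;
  the subset filter expression is recorded verbatim in every output row.
* Kruskal–Wallis with tie correction, then pairwise Mann–Whitney with BH
  within the pairwise family.
* Disease × serostatus interaction: OLS of the variable on disease,
  stratum, their product, age and sex; Wald p on the product term; errors
  on empty design cells.
* MMSE severity trend: Jonckheere–Terpstra across ordered groups
  (HC, 25–30, 20–24, 10–19, <10), ascending cross-group pairs with ties
  half-weighted; exact p by enumeration for total n ≤ 10, otherwise the
  normal approximation (no-tie variance). Chosen over a linear-on-ordinal
  regression because the expected pattern is a monotone step-wise shift,
  not a linear one.
* Correlation-structure deviation: Pearson r per group and Fisher-z
  difference z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), BH across
  the supplied variable pairs.

Exact-vs-approximate switchover constants (12 and 10) are desk-scale
exactness choices, recorded as module constants.

## Synthetic cohort generator

Frequencies are `min(exp(μ_j + s_j · latent_ij), 100)` with
μ_j ~ U(ln 0.05, ln 20) and s_j ~ U(0.3, 0.6); the latent score is

    latent = β_age,j · z(age) + β_sex,j · 1[male] + d_j · m(MMSE) · 1[AD]
             + noise,

with unit-variance noise that, for shared-environment variables, splits
into a pair-level component (variance share ρ) and an individual residual.
Because log + z-score inverts the link exactly, a planted d_j is the
standardized mean difference on the transformed scale for a patient in the
reference band (10–19, multiplier 1.0); the severity ladder (0.4 / 0.7 /
1.0 / 1.3 across improving→worsening cognition bands, configurable)
emulates a step-wise gradient, and under the default clinic band mix the
marginal AD–HC difference is ≈ 0.85 · d_j. Ages are clipped normal
(69, 9²) on [45, 83] for both groups; spouse ages track their partner's
with 3-year jitter (realistic spousal gaps); spouses are opposite-sex.
Missingness is MAR given the baseline: per-variable probability
∝ the survival percentile of μ_j, rescaled to the base rate (default 5 %)
and capped at 0.9 — rare populations miss most, and the probability is
monotone non-increasing in baseline frequency by construction.

Default truth (`default_truth`): four affected variables named for the
gates such a study reports (three depressed B-cell maturation populations
and a T-bet⁺ CD8 effector-memory gate) with d = −0.8…−0.5, a ρ = 0.3
shared-environment component on 30 unaffected variables (moderate
cohabitation effect), weak age slopes (SD 0.15) on ~10 % of variables,
and 5 % base missingness. Effect sizes are chosen for test power — no
interpretable effect scale is available for the real panel — and are not
claims about real effect magnitudes.

**What the generator does not emulate:** gating-tree compositional
constraints between parent and child populations, batch/acquisition-day
effects, heavy-tailed technical outliers, missingness that depends on the
unobserved value itself (MNAR), and biomarkers correlated with immune
variables. Passing recovery tests therefore demonstrates the pipeline's
correctness and calibration under the stated statistical anatomy, not
robustness to those real-data features.

## Reproducibility

One master seed expands into fixed per-stage offsets
(`RunConfig.stage_seed`), so a stage rerun in isolation reproduces the
full-pipeline result; identical (input, config, seed) gives byte-identical
outputs, and every output carries the config hash and master seed. The
synthetic benchmark sizes (cohorts of 80–600 subjects, 20–400 variables,
curves to N = 12, 59–199 simulated pairings, 20-seed repetition) were
chosen so each check is statistically decisive at desk scale; all are
parameters, not constants.

## Known limitations

* Imputation and transform parameters are estimated once on all subjects,
  then frozen through CV (mild optimism; the honest-nested mode addresses
  ranking leakage only).
* The permutation null is slightly anticonservative by construction
  (add-one corrected; measured 0.045–0.065 depending on matcher dispersion) because the constraint-preserving
  sampler cannot be perfectly exchangeable with the actual pairing while
  also avoiding it; the add-one correction bounds the effect.
* Single imputation: no propagation of imputation uncertainty.
* The Jonckheere–Terpstra normal approximation uses the no-tie variance;
  with heavy ties at moderate n its p is approximate.
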