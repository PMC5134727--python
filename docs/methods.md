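# Methods

This note documents the statistical machinery in `wgpred`, the assumptions
behind the synthetic cohort generator, the numerical choices, and the
limitations a user should keep in mind when carrying conclusions from
synthetic cohorts to real data.

## Quality control

SNPs are filtered in the fixed order **autosome → MAF → HWE**, with the
order recorded in the `QCReport` (the order is a package choice; it affects
per-filter counts, not the final set, for independent criteria). Minor
allele frequency is folded (min(p, 1−p)) and computed from non-missing
dosages over the whole cohort, cases and controls pooled, as in a
single-cohort design. Hardy–Weinberg equilibrium uses a 1-df chi-square
goodness-of-fit test of observed genotype counts against expectations from
the sample allele frequency (monomorphic SNPs return p = 1); a conditional
exact test is available via `hwe_test(..., method="exact")` for users who
prefer it at low counts. Defaults: MAF ≥ 0.05, HWE p ≥ 0.001. Missing
genotypes and phenotype/covariate cells are imputed with the column mean
(mode for categoricals), which shrinks association signal toward the null
rather than inventing it.

The PLINK 1 bed/bim/fam codec (v1.00 magic `6c 1b`, SNP-major, 2-bit
genotypes with the subject index in the low bits first) is implemented
in-package and covered by a byte-level round-trip test plus a hand-decoded
fixture. A plain-text dosage dialect (header of SNP ids, one row per
subject, `NA` for missing) serves as a human-readable interchange format.

## Genomic relatedness

The GRM is the weighted average of products of centered, standardized
dosages,

    A_jk = Σ_i w_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)) / Σ_i w_i.

Normalizing by Σ w_i keeps the diagonal near 1 under any weighting scheme,
so REML variance components and kriging ridges remain on a comparable
scale; the matrix is invariant to any positive rescaling of the weights.
Scheme weights act **in conjunction with** the inverse-variance
standardization (they multiply standardized contributions); passing
`standardize=False` instead applies weights to raw centered dosages for
users who want weights to **replace** the default. The NZW scheme is pure
subsetting: SNPs with zero total priority score are removed and the
retained set gets standard weights.

Centering frequencies default to the full cohort, including subjects later
held out — this mirrors the leave-one-out protocol in which the GRM is
built once on everyone; `compute_grm(allele_freqs=...)` supports a strict
no-leakage mode with training-only frequencies.

Genotype principal components are eigenvectors of the double-centered
kinship matrix scaled by the square root of their eigenvalues (six by
default). Covariate similarity one-hot encodes categoricals, standardizes
columns, and averages cross-products — the same algebra as the GRM with
unit weights — and covariate integration is an entrywise convex
combination of kernels (equal mixing by default, overridable).

## GREML

`greml_fit` maximizes the restricted likelihood of
y ~ N(Xβ, σ²_g A + σ²_e I) over the two variance components. The GRM is
eigendecomposed once per fit; all subsequent algebra is diagonal, so each
iteration costs O(n) after the O(n³) decomposition. Updates are
average-information steps with step-halving, falling back to an EM-type
step whenever the AI step loses likelihood or leaves the parameter space;
components are floored at 1e-6·var(y) and a floor-pinned solution is
flagged `boundary`. Convergence is |Δ log L| < 1e-6 within 100 iterations.

Because a two-component model profiles exactly to one dimension — at fixed
h² the REML-optimal total variance is y'P_R y/(n−p) — the fit ends with a
bounded Brent search over h² followed by a few Newton/AI polish steps.
This rescues the slow linear EM crawl near variance boundaries (where
AI-REML alone can stall below the optimum) and makes the returned optimum
reproducible to machine precision under shifts and rescalings of y.
`profile_refine=False` exposes the raw iteration path, in which case an
iteration-capped fit is returned flagged `converged=False` rather than
silently.

The standard error of h² comes from the delta method applied to the
inverse average-information matrix at the optimum. The test of h² = 0 is a
likelihood-ratio statistic against the closed-form null (V = σ²I, REML
variance RSS/(n−p)) referred to the boundary mixture ½χ²₀ + ½χ²₁. Both
failure modes of a heritability estimate — boundary pinning and iteration
cap — are reported distinctly.

Dichotomized traits are analyzed on the observed 0/1 scale; `liability_h2`
offers the post-hoc liability-scale conversion, off by default.

## Prediction

`gblup_predict` solves (K_tt + λI) α = y − 1β̂ on the training block and
scores test subjects as K_xt α + β̂. The intercept β̂ is estimated by GLS
under V = K_tt + λI, which makes the scores exactly equal to a direct
mixed-model-equations solve (the package's choice of centering; plain
training-mean centering is available via `center="mean"`). The ridge
defaults to σ̂²_e/σ̂²_g from a REML fit when one converges, and to 1 — the
value implied by an agnostic prior h² of 0.5 — otherwise.

Leave-one-out prediction computes M = (K + λI)⁻¹ once and obtains every
per-subject refit exactly through the bordered-inverse identity

    score_j = y_j − (My)_j / M_jj + β̂_j (M1)_j / M_jj ,

with β̂_j the holdout GLS intercept from Schur-complement sums — O(n³)
total instead of O(n⁴), verified against naive per-subject refitting to
1e-10.

A deliberate consequence of the per-holdout intercept (inherent to "LOO
equals per-subject refitting"): on a trait with **no** genetic signal the
LOO scores anti-correlate slightly with the held-out labels, because each
holdout's intercept excludes that subject's own label. The null LOO AUC
therefore falls **below** 0.5 (≈0.2 at n = 800 when the kinship carries no
information) rather than sitting at it. This is conservative for the
one-sided permutation test (observed AUC below the permutation null) and
does not disturb the monotone increase of LOO AUC with true h², but null
LOO AUCs should not be read as miscalibration.

`kriging_simple_predict` is the weighted-sum form without a system solve:
score = Σ_t w_xt (y_t − ȳ) + ȳ with w ∝ K_xt over the k nearest training
subjects (all by default) normalized by Σ|w| (the chosen convention for
handling negative similarities; configurable).

Baselines: per-SNP categorical naive Bayes with add-one smoothing (score =
posterior log-odds; imputed dosages rounded), L1-penalized logistic
regression with the penalty chosen by cross-validation strictly inside the
training fold (scikit-learn optimizer), and a linear-kernel SVM on
standardized dosages. All baselines consume the QC'd SNP set without
association pre-filtering.

## Evaluation

AUC is the Mann–Whitney probability that a case outscores a control, ties
counting ½ — exact, computed from ranks. The convex-hull AUC integrates
the upper convex hull (Andrew monotone chain) of the empirical ROC points
including (0,0) and (1,1); it always dominates the raw AUC and equals it
on concave ROCs. Permutation p-values use the add-one estimator
p = (1 + #{AUC_perm ≥ AUC_obs})/(B + 1) against the one-sided alternative
AUC > 0.5, so p is never zero and the test is at worst super-uniform by
1/(B+1). The repeated-split protocol draws stratified 75/25 splits
(stratification keeps both classes in every test set; an unstratified mode
exists), 25 repeats by default, and reports means and standard deviations
of AUC and convex-hull AUC plus the mean permutation p. Averaging p-values
across repeats is statistically unconventional but is the protocol's
reporting convention; users wanting a single combined test can apply e.g.
Fisher's method to the per-repeat p's in `EvalResult.per_repeat`.

## Phenotype derivation

Continuous traits are dichotomized about the mean (label 1 strictly above).
Bronchodilator response is (post − pre)/pre on pre-bronchodilator FEV₁ > 0.
The lung-pattern classifier consumes per-visit (age, %pred FEV₁,
percentile-rank) series with ≥ 4 visits: base class NG if strictly more
than half the observations sit above the 25th percentile (the "predominately"
rule is a majority by default and configurable, as the qualitative
criterion does not pin a fraction), else RG; early decline requires
follow-up to at least age 23 and a relative drop of ≥ `decline_threshold`
(default 0.05, a documented stand-in — the defining magnitude lives in the
longitudinal-phenotype literature, not here) from a rolling-median-smoothed
peak attained before the final visit. Composites: ED-All = {NG-ED, RG-ED},
RG-All = {RG, RG-ED}; the four base labels are mutually exclusive and
exhaustive over classifiable subjects.

## Synthetic cohort generator

The generator emulates the study conditions of a pediatric asthma cohort:

- **Genotypes** — m SNPs with frequencies uniform on [0.05, 0.5] (the
  post-QC spectrum), dosages Binomial(2, p) i.i.d. across subjects (HWE by
  construction, so ≈ 99.9% pass the 0.001-level HWE filter and ≈ 100% pass
  the MAF filter). Defaults n = 832 subjects, m = 5000 SNPs — the cohort
  size of the emulated study with the marker count scaled to desk size.
- **Trait** — effects i.i.d. Gaussian on standardized dosages over a
  causal subset (default 5% of SNPs); noise scaled against the realized
  breeding-value variance so the realized h² is centered on `h2_true`.
  This matches the GREML generative model, making recovery tests
  well-posed.
- **Priority scores** — total score in [0, 0.12] split into a
  regulatory-evidence component (Beta-distributed) and a MAF component
  (∝ MAF); a zero-score mass (default 0.431, matching the observed
  retention of 259,156 of 455,481 SNPs under the functional
  prioritization) assigned by weighted sampling in which causal SNPs'
  retention odds are multiplied by (1 + informativeness). Informativeness
  0 makes scores independent of causal status; the default 4.0 represents
  strongly informative functional evidence.
- **Covariates** — age, age at diagnosis, sex, treatment arm, height, BMI,
  vitamin D, race/ethnicity drawn to match the emulated cohort's
  demographic table; effects on the trait are zero by default and settable
  per covariate. Missingness is MCAR (no mechanism is specified for the
  real data; MCAR plus mean imputation biases toward the null).
- **Trajectories** — annual %pred FEV₁ from age 6 to 25 against an
  internal Gaussian reference (mean 100, SD 12 — classification only needs
  relative position, so a synthetic reference substitutes for published
  growth equations): NG level 108 (above the 25th percentile ≈ 91.9), RG
  level 80, a ramp to a plateau at age 15, and for ED patterns a 12%
  decline from a peak at age 20. Pattern assignment marginals default to
  the emulated cohort's: NG 26.6%, NG-ED 20.6%, RG 26.7%, RG-ED 21.3%,
  remainder unclassifiable. Per-visit Gaussian noise is optional; the
  trajectory shape and noise parameters are free choices of this package,
  as the source phenotype definitions are qualitative.

All randomness flows from the single config seed through named CRC-keyed
substreams, so identical configs are bitwise reproducible and pipeline
stages (splits, permutations, simulation) can share randomness across
scheme comparisons — required for paired comparisons.

**What the generator does not emulate:** linkage disequilibrium between
SNPs (markers are independent), population stratification (available only
as an explicit two-population construction in tests), genotyping error,
informative missingness, and selection into the cohort. Two consequences
matter for interpreting results. First, passing recovery tests here shows
the estimators are correct under their own model, not that real cohorts of
n ≈ 800 yield precise heritabilities — at that sample size standard errors
of 0.2–0.3 are expected, as the emulated study itself reports. Second,
without LD, removing a random subset of SNPs removes the corresponding
share of tagged heritability: under **uninformative** priority scores the
NZW scheme therefore strictly loses accuracy (measured ≈ −0.01 to −0.02
AUC), where on real, LD-redundant panels the loss would be buffered by
neighboring markers. The informative-scores NZW gain (≈ +0.02 AUC at
default conditions) is the meaningful direction check.

## Problem sizes

Test-suite and acceptance-script experiment sizes are chosen so each
experiment carries enough replicates for its assertion while the whole
suite stays desk-scale: GREML recovery and null calibration at n = 1000,
m = 2000 with 20 replicates; the AUC-vs-h² curve at n = 800, m = 2000 with
10 replicates per level; scheme comparisons at the generator defaults
(n = 832, m = 5000) with 25 shared-seed replicates; permutation
calibration over 400 trials of 99 permutations.
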