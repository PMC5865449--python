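# Methods

## The twin model

The unit of analysis is the twin pair with the 4-vector
(victim_A, offend_A, victim_B, offend_B). Under the classical twin design
the model-implied covariance is

    Σ_zyg = [ A + C + E      wA + C    ]
            [ wA + C         A + C + E ],   w = 1 (MZ), 0.5 (DZ),

where each of A, C, E is a 2×2 factor covariance built from a
lower-triangular Cholesky block L_f (A = L_A L_Aᵀ, etc.). Assumptions:
additive gene action with a DZ genetic correlation of exactly 0.5, equal
trait-relevant environments for MZ and DZ pairs (untested, as usual for
this design), no assortative mating, no gene-environment interaction or
correlation, and exchangeable twins within a pair.

Phenotypes are modeled as continuous variables. Variety scores (counts of
distinct victimization/offending types) are treated on their raw scale by
default, matching the Pearson-correlation reporting convention of this
literature; the generator also exposes the underlying normal liabilities,
so either scale can be analyzed, and a rank-based transform can be applied
upstream if desired.

**Estimation.** Sufficient statistics (per-zygosity mean and MLE
covariance of the 4-vector) are symmetrized over twin order, which is the
moment-space equivalent of constraining the two cross-twin cross-trait
correlations to be equal. The Gaussian −2·log-likelihood is minimized over
the nine Cholesky loadings (diagonals bounded ≥ 0; the E diagonals bounded
strictly positive so Σ stays positive definite) and two per-trait means by
L-BFGS-B with numerical gradients, followed by a short Nelder-Mead polish
that guards against stalls at an active bound. Starting values come from
Falconer's estimators a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ applied per
trait. The objective is normalized per pair so optimizer tolerances
(ftol 1e-15, gtol 1e-9) are scale-free. Moment-matrix input (a 4×4 matrix
plus pseudo-N per zygosity) uses the same discrepancy with means fixed,
which makes "ML at the population moments recovers the truth" an exact
self-consistency oracle — the core correctness check of the fit.

Submodels AE, CE, E fix the dropped factor's block at zero; models are
ranked by AIC = −2lnL + 2k and likelihood-ratio statistics against ACE are
reported. Descriptive twin correlations are computed on the double-entered
pair set (invariant to twin order, pools the two cross-trait directions)
with Fisher-z confidence intervals using the number of families — not
2n — as the effective sample size.

**Correlated factors and path tracing.** Standardized components are
f²_t = (variance of trait t from factor f) / (total variance of t); the
factor correlation uses the published formula, which reduces to
r_f = f21/√(f21² + f22²) for a 2×2 block. The formula is indeterminate
when a factor loads on only one trait; the package defines r_f = 0 there
(with a warning when the degenerate direction could not arise from a
proper Cholesky). The covariance share of factor f is
√(f²_v f²_o)·r_f divided by the sum over factors; the sum itself is the
implied phenotypic correlation. The inverse transform
(f11, f21, f22) = (√(f²_v V_v), r_f √(f²_o V_o), √(f²_o V_o (1−r_f²)))
round-trips to 1e-9, which is tested property-style.

**Confidence intervals.** The default is a nonparametric bootstrap that
resamples families within zygosity (B configurable, 1000 by default in the
CLI; degenerate replicates are dropped and counted). Percentile intervals
automatically respect the natural bounds ([0,1] for components, [−1,1]
for correlations). A profile-likelihood alternative is provided
(equality-constrained refits via SLSQP, bisected to the χ²(1) cutoff);
neither method is privileged because the interval construction used for
the published estimates is not documented beyond its level.

## The synthetic cohort

The generator draws, per family, standard-normal factor scores: genetic
scores correlated 1.0 (MZ) or 0.5 (DZ) across co-twins, shared-environment
scores identical within a family, unique-environment scores independent;
each factor's two trait components are mixed through the Cholesky block of
the generating correlated-factors solution. Liabilities are therefore
exactly multivariate normal with the textbook twin covariance, and every
printed correlation identity (MZ within-trait → a²+c², DZ → a²/2+c²,
cross-twin cross-trait → a_v a_o r_A + c_v c_o r_C, etc.) holds in
population; tests verify them at 20 000 pairs within Monte-Carlo error.

Defaults are the study conditions: 1116 pairs, 55% MZ, 49% male (sex
constant within a family — same-sex pairs), generating solution
a²/c²/e² = 0.31/0.19/0.50 (victimization) and 0.33/0.22/0.45 (offending)
with factor correlations 0.28/0.86/0.33, margins 48% prevalence / mean 1.52
(victimization, max 20) and 50% / 1.74 (offending, max 33).

**Counts.** Variety scores are a monotone image of liability: zero below
the threshold Φ⁻¹(1 − prevalence), and above it a quantile map onto a
truncated-geometric distribution on {1..max} whose decay parameter is
solved (Brent) so the overall mean matches the margin. The geometric shape
is a modeling choice: only prevalence and mean are published, and a
geometric-like right skew is what variety-score distributions in this
literature look like. Infeasible margins (positive-part mean outside
(1, max)) raise a calibration error naming the margin.

Any monotone map to these margins attenuates Pearson correlations relative
to the liability scale; with 52%/50% zero mass the per-trait attenuation
factor is κ ≈ 0.83 (computed exactly from E[Z·g(Z)]). Consequences worth
stating plainly:

* the population count-scale correlation implied by the liability
  correlation 0.422 is ≈ 0.345 (exact 2-D Gauss-Hermite value, exposed as
  `population_count_correlation` and tested against samples). A single
  Gaussian-copula liability model cannot simultaneously reproduce a
  count-scale r of 0.42, the 48%/50% margins, and a 29% victim-offender
  share — the published figures imply dependence slightly stronger in the
  positive tails than at the zero boundary. The generator keeps the
  liability scale exact and lets the count scale attenuate.
* the implied four-group split is ≈ 33/17/19/31% against the published
  35/16/20/29%; the victim-offender share is reproduced to about two
  percentage points.
* configured risk-factor loadings are interpreted on the observed count
  scale and de-attenuated internally (divided by κ per trait), so sample
  risk-phenotype correlations land on their targets. Binary items apply
  the same loadings to a latent normal thresholded at the configured
  prevalence; their observed point-biserial correlations attenuate further
  by the usual thresholding factor, which is accepted (only group-ordering
  and prevalence claims depend on them). Jointly infeasible loading pairs
  (implied noise variance < 0) raise a calibration error naming the risk.

Continuous risks are reported on interpretable scales (IQ-like cognitive
ability, a 1–5 pubertal-timing scale) via affine maps from the generated
z-scores; the correlation targets are scale-invariant.

**Seeding.** One master seed drives a single documented stream order
(phenotypes first; risk columns from a child stream spawned as
SeedSequence([seed, 1])), so identical config + seed reproduces the cohort
byte-for-byte, which is asserted in tests.

**What the generator does not emulate:** attrition and missing data,
item-level responses, reporter effects, sex differences in means or in the
twin architecture, non-normal liability dependence (see above), and any
causal pathway from the risk factors to the phenotypes — risks are
correlated with the liabilities by construction, not mechanistically.
Passing tests therefore certify the statistical machinery and its
calibration, not substantive conclusions about real cohorts.

A separate direct-mechanism simulator (`simulate_outcome_cohort`) is used
for logistic-recovery studies: family-clustered ACE counts (gamma-Poisson
with a family frailty), sex constant within family, and a binary group
outcome drawn from a specified per-ACE odds ratio on the logit scale. It
exists because the structural generator has no per-ACE causal odds
parameter to recover.

## Variable- and person-centered analyses

Partial correlations use the first-order formula and are tested to 1e-12
against the two-stage residual-regression oracle. Percent reduction is
computed against the analysis cohort's own unrounded zero-order
correlation. Family clustering is handled by a cluster bootstrap over
families (the same resample reused across quantities), since the original
adjustment method is described only as "adjusted for clustering"; the
bootstrap interval is never narrower than the naive i.i.d. interval on
positively within-family-correlated data, which is asserted on simulated
cohorts. Missing values: pairwise deletion per row; constant columns are
flagged, never silently dropped.

Group contrasts: Tukey's HSD on the one-way four-group layout for
continuous rows; for binary rows, chi-square without continuity correction,
switching to Fisher's exact test when any expected cell is below 5, with
Benjamini-Hochberg adjustment applied within each row's three
victim-offender contrasts. Logistic models use statsmodels with
family-cluster-robust (sandwich) covariance; model 2 adds the raw
victimization (or offending) variety score as a covariate for the
victim-only (offender-only) contrast. Separation is detected (diverged
coefficient or SE, or optimizer failure) and flagged rather than reported.

Summary-scale quartile cutoffs are empirical quantiles of the analyzed
cohort, with values equal to the cutoff included in the extreme group
(ties inflate the flagged share above 25%, as documented and tested).

## Problem sizes and numerical tolerances

Monte-Carlo checks of population identities use 20 000-pair cohorts
(absolute tolerances 0.03–0.04, about 4 standard errors). Self-consistency
moment fits use pseudo-N = 10⁶ and are checked to 3 decimals. Calibration
summaries average 20 study-sized cohorts; logistic recovery averages 100
fits at the published contrast size (n = 858). Bootstrap B defaults to
1000 in the CLI and is reduced in tests, where only determinism, coverage
behavior and interval width — not tail accuracy — are asserted.

## Known limitations

* Ordinal/liability-threshold estimation for the counts is not
  implemented; the continuous treatment slightly biases components toward
  E on the count scale (the liability scale is exact).
* No sex-limitation models, no extended pedigrees, no more than two
  phenotypes.
* Profile-likelihood intervals use numerically constrained refits and are
  slower and less robust near parameter bounds than the bootstrap default.
* Significance markers in the reduction table are bootstrap p-values; no
  claim is made that they replicate any particular clustered-test
  construction.
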