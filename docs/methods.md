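# Methods

## Scores and factorial arms

A weighted genetic risk score is `GRS_i = Σ_v w_v d_iv` over the variants
of one lipid pathway, with dosages `d` in [0, 2] counting the
lipid-lowering (effect) allele. Score definitions are oriented at load
time: any variant supplied with a negative weight has its alleles swapped
and weight negated, so stored weights are positive and a higher score
always means genetically lower lipid. When the dosage file's coded allele
is the score's other allele, the dosage is reflected (`d → 2 − d`);
scores are exactly invariant under this re-coding, which is tested.
Missing dosages are imputed as twice the effect-allele frequency
estimated from non-missing individuals — unbiased under missingness
completely at random, which is also the generator's missingness
mechanism. Standardized scores divide by the within-cohort SD, so
reported per-score effects are per SD of score.

Each of k scores is dichotomized at its within-cohort median
(indicator = 1 for score ≥ median, i.e. the genetically lower-lipid
arm), giving 2^k arms; the all-zero arm is the reference. The `≥` tie
rule is deliberate: a two-variant score built on common lowering alleles
is highly discrete and masses many individuals exactly at the median
(the simulated *APOA5* score splits roughly 75/25 for this reason, and
its median-split gap in standardized units is correspondingly wider than
the normal-score value 2√(2/π) ≈ 1.60). The rule, and explicit
thresholds, are exposed as options. A constant score raises rather than
silently producing a degenerate split.

CAD status can be derived from ICD-10 code lists: case iff any code's
3-character root is I20, I21, I22, I24 or I25; sub-codes match by root
and unrecognized codes are ignored.

## Regression models

- CAD: logistic regression of case status on the 2^k − 1 non-reference
  arm indicators plus covariates (default age, sex, 10 principal
  components), fitted by IRLS (statsmodels GLM; max 50 iterations, a
  post-fit score-norm check). Perfect separation and rank-deficient
  designs raise explicit errors — collinear terms are named, never
  silently dropped. Wald SEs, p-values and exp-transformed ORs/CIs.
- Metabolites: each measure is rank-based inverse-normal transformed,
  `Φ⁻¹((r − 3/8)/(m + 1/4))` with average ranks for ties (Blom offset,
  configurable), then regressed on the arm indicators plus covariates
  (default age, sex, 4 PCs). Values below a detection limit are set to
  missing first and simply reduce each fit's n.
- Weights: frequency weights reproduce row duplication; probability
  (sampling) weights use weighted estimation with HC0 sandwich standard
  errors, appropriate for designed oversampling.
- Interaction: `outcome ~ A + B + A·B + covariates` on the *continuous*
  scores; the product term's Wald test judged against the multiplicity
  threshold. Under an additive generative model its type-I error is
  calibrated (checked at α = 0.05 over 200 replicates).

## Multiplicity

The Li & Ji effective number of tests eigendecomposes the Pearson
correlation matrix of the transformed measures (pairwise-complete by
default, to use censored data maximally; complete-case is a switch) and
sums `f(|λ|) = 1{|λ| ≥ 1} + (|λ| − ⌊|λ|⌋)`. Eigenvalues are snapped to
nine decimals before the floor so that a rank-deficient matrix whose top
eigenvalue is numerically 2.999999… counts as exactly one test; without
this the floor discontinuity can double-count. `m_eff` is rounded to the
nearest integer for the threshold `α/m_eff` (raw value also reported).
Non-PSD pairwise matrices are clipped at zero with a warning.

## Meta-analysis

Cohorts are analyzed separately and pooled two-stage by inverse-variance
fixed-effect weighting — covariate scales differ across studies, so no
individual-level pooling. Cochran's Q is set to exactly zero when all
inputs agree (avoiding floating-point dust) and I² = max(0, (Q − df)/Q).
A single-cohort input passes through with a warning. The implementation
is cross-checked against statsmodels' `combine_effects` in the tests.

## Effect summaries

OR = exp(β), CI = exp(β ± 1.96·SE). Risk reduction is reported two ways:
the rare-outcome approximation `100·(1 − OR)` and the Zhang–Yu
incidence-corrected `RR = OR/((1 − p₀) + p₀·OR)` — the CAD case fraction
(~11.7%) sits above the usual <10% rule-of-thumb, so both conversions are
always emitted rather than committing to one. Additivity is assessed by
comparing the joint-exposure OR with the product of the single-exposure
ORs (multiplicative scale) and the summed single-arm risk reductions
with the joint reduction (difference scale).

## Synthetic cohorts

The generator exists so the full pipeline can be validated by parameter
recovery; its defaults encode the study conditions of a large European
biobank plus two metabolomics cohorts:

- Genotypes: binomial(2, f) per variant — Hardy–Weinberg, linkage
  equilibrium (the real scores use variants selected to be independent,
  so LD is deliberately not simulated). Default panel: 2 *APOA5* and 5
  *LPL* TG variants, 15 LDL-C variants, with frequencies and weights of
  realistic magnitude (actual weights are user data).
- Phenotypes: TG and LDL-C linear in the standardized scores
  (defaults −0.25/−0.15 SD per SD for *APOA5*/*LPL* on TG, −0.30 for the
  LDL-C score on LDL-C) plus Gaussian noise; age ~ N(56.8, 8.0),
  sex ~ Bernoulli(0.43), BMI ~ N(27.4, 4.8), 10 standard-normal PCs.
- Metabolites: 145 measures = score effects + unit-variance Gaussian
  noise with compound-symmetric blocks (sizes 20/15/20/20/30/40,
  correlations 0.65–0.90 standing in for lipoprotein subclass families).
  Default effect vectors share a lipoprotein pattern (lower VLDL/LDL,
  higher HDL) with *APOA5* effects roughly twice *LPL*'s and an extra
  HDL component for *LPL*; magnitudes are set so the joint lower-TG
  arm's strongest contrast is ≈ −0.3 SD and the panel's effective test
  count is of the order a Nightingale-style panel shows (defaults give
  m_eff ≈ 40–50 at n ≈ 5,000). Detection-limit censoring removes exactly
  ⌊q·n⌋ lowest values per measure.
- CAD: Bernoulli with logit = intercept + per-SD score effects + age,
  sex and BMI terms; the intercept is solved by root-finding so the
  marginal incidence hits the target (default 0.117), with a diagnostic
  error if unreachable. Default per-SD log-ORs are
  ln(0.95)/1.596, ln(0.94)/1.596 and ln(0.87)/1.596 for
  *APOA5*/*LPL*/LDL-C, i.e. chosen so normal-score median-split arm
  contrasts land at odds ratios about 0.95, 0.94 and 0.87.
- Oversampling: BMI strata with sampling multipliers; each row is drawn
  with expected multiplicity equal to its stratum multiplier (floor +
  Bernoulli fractional part), and the biased sample carries
  Horvitz–Thompson weights 1/multiplier. The stratum *count* scales by
  the multiplier (the stratum *fraction* scales by m/(1 + (m−1)π), which
  is what resampling algebra implies). An optional per-stratum TG-effect
  multiplier creates effect heterogeneity so weighting can be validated:
  the weighted fit recovers the population-average effect the unweighted
  fit of the biased sample misses.

All randomness flows from one integer seed through per-operation
`numpy` Generator streams; identical configurations are bit-identical.

What the generator does **not** emulate: linkage disequilibrium,
imputation dosage uncertainty, population stratification beyond
independent PC covariates, non-Gaussian metabolite tails beyond what the
rank transform removes, and informative missingness. Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed structure, not robustness to those real-data complications.

## Numerical choices and test design

- Logistic convergence: IRLS tolerance 1e-10, cap 50 iterations;
  separation detected via statsmodels' perfect-separation warning,
  diverging coefficients (|β| > 30) or an unconverged score norm.
- Rank checks use `numpy` matrix rank plus pivoted QR to name the
  collinear columns.
- The saturated 2×2 logistic fit is required to match the closed-form
  cross-product OR to 1e-8; linear fits match a normal-equations oracle
  to 1e-10; GRS computation matches a per-individual loop oracle.
- Problem sizes in the test suite are chosen to keep the full run in a
  few minutes: recovery of the 145-measure group contrasts is assessed
  on coverage pooled over ten replicate two-cohort pipelines of 20,000
  individuals each, because block-correlated measures make any single
  panel's ±2 SE coverage fraction volatile (its expectation is 95.4%;
  pooling replicates is the statistically sound way to test a ≥95%
  coverage bar). Type-I error checks use 200 seeded replicates.
- The acceptance script simulates at the reference sample sizes
  (309,780 for the 2×2×2 CAD analysis; 4,838 + 6,999 for the pooled
  metabolome analysis) and reports every quantity on the scale the field
  prints (ORs, percentages, counts of significant measures).

## Known limitations

- Pairwise-complete correlations can produce non-PSD matrices; they are
  clipped, not re-projected to the nearest correlation matrix.
- The rank-based transform is a within-cohort normalisation; fitted
  transformer state does not map out-of-sample data.
- `m_eff` depends on the data actually supplied (per input table); with
  heavy censoring the pairwise estimate can differ from complete-case.
- The factorial contrasts estimate arm differences, not the causal
  effect of TG itself; no mediation analysis is attempted.
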