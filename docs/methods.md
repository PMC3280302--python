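# Methods

## The analysis

`bmilong` analyses repeated body-mass-index (BMI, kg/m²) measurements on a
cohort of subjects genotyped at a small candidate panel of SNPs (the built-in
panel holds 23 GWAS BMI loci with their minor-allele frequencies). The
longitudinal observations are split into a childhood stratum (measurement age
< 18 years) and an adulthood stratum (≥ 18 years); a subject can contribute to
both. Four connected analyses are provided:

1. **Single-SNP scans.** Each SNP is tested for a main effect on BMI in a
   linear mixed model, and for a cross-sectional effect on birth weight in an
   ordinary linear model (gestational age and sex controlled).
2. **Interaction tests.** Genotype × age and genotype × birth-weight product
   terms added to the mixed model, tested jointly by Wald chi-square.
3. **Forward burden search.** A greedy construction of an unweighted
   allele-burden score whose per-step acceptance criterion is a modified AIC,
   with an empirical permutation p-value for the selected model.
4. **Power.** Analytic power of the design by variance explained, with the
   Bonferroni-adjusted per-test alpha.

## The mixed model

For subject *i* with observations *j*:

    BMI_ij = β0 + β_age age_ij + β_sex sex_i + β_bw bw_i + genetic term(s)
             + b0_i + b1_i age_ij + ε_ij

with (b0, b1) bivariate normal (unstructured 2×2 covariance) and ε iid normal.
The "random effect of age" is implemented as a correlated random intercept +
random age slope because growth data have both between-subject level
differences and between-subject slope differences; slope-only and
intercept-only structures are available via `MixedLMM(random_structure=...)`.

Estimation is **maximum likelihood, not REML**: the association scans and the
forward search compare models that differ in fixed effects, where REML
likelihoods are not comparable, and the modified AIC is defined on the
maximized likelihood. The likelihood is profiled — for a fixed residual-scaled
random-effect covariance Ψ, the GLS fixed effects and ML residual variance are
closed-form — leaving a 3-parameter optimization over the log-Cholesky factors
of Ψ, done by Nelder-Mead with the per-subject algebra reduced to 2×2 blocks
through the Woodbury identity (a numba kernel; a single fit costs a few
milliseconds, which is what makes permutation re-search feasible). Correctness
is pinned by two independent oracles in the test suite: brute-force evaluation
of the marginal multivariate-normal density on tiny instances, and statsmodels
`MixedLM(reml=False)` / lme4 ML fits on moderate data (agreement ~1e-6 in lnL
where the reference converges; our optimizer is never worse).

Ages enter raw (uncentered, years), so interaction coefficients read as effect
change per one-year increase in age; birth weight is in kg.

### Genetic codings

* **additive** — dosage 0/1/2 of the minor allele, one coefficient (1-df test);
* **general** — genotype as a 3-level factor, heterozygote and minor-homozygote
  coefficients against the major-homozygote baseline (2-df Wald test).

A SNP missing a genotype class in a stratum is tested additively only and
flagged. For reporting, general-model effects are re-expressed against
whichever homozygote has the lower adjusted mean (a reporting transform only;
the fitted design keeps the major-homozygote baseline for stability).

### Multiple testing

q-values are computed per (stratum × coding) family over the panel
(Benjamini–Hochberg step-up by default; a Storey π₀-adjusted variant is
available but is not the default because 23–46 tests are few for π₀
estimation). The per-variant q is the smaller of the two codings' q-values.
Families are not pooled across strata because childhood and adulthood are
reported as separate analyses; the family definition is a function argument.

## The forward burden search

State: an ordered set of (SNP, reference allele) pairs and the per-subject
burden = Σ counts of the chosen reference alleles. At each step every
(remaining SNP × two alleles) candidate is evaluated by refitting the full
mixed model with the trial burden as the single genetic covariate and scoring

    modified AIC = 2 (k + n_non_snp) − 2 ln L,

where k is the number of selected SNPs and n_non_snp = 4 fixed covariate
coefficients + 4 variance components = 8. The burden coefficient itself is
*not* counted again — the model is penalized per SNP aggregated into the
score, which is precisely what distinguishes this from the ordinary AIC.
Because n_non_snp is constant across compared models it shifts every score
equally and never changes a selection. The search accepts the minimum-AIC
candidate iff it is strictly below the current AIC (any ε > 0; no minimum
decrease), freezes accepted SNPs (no backward steps, no allele re-choice), and
stops otherwise.

**Tie-breaking.** At step 1 the two allele orientations of a SNP give affinely
identical designs (the intercept absorbs the shift burden → 2k − burden), so
their AICs tie structurally. Ties (within 1e-5, above the float noise between
the two computations) are broken toward the allele with a positive burden
coefficient — the risk-allele reporting convention — then toward the lower
panel index. Candidates that fail to converge or whose burden is constant are
unavailable at that step.

**Variance trace.** Per accepted step the trace records the cumulative
explained variance 100·Var(β̂·S)/Var(BMI) over observations (S the burden,
β̂ its coefficient) and the single-variant analogue from a one-SNP burden fit.
This definition is one of several possible "explained variance" readings; it
is documented here because near-zero first-step values (β̂ ≈ 0) are possible
and expected — minimizing AIC is not the same as maximizing the single-SNP
effect.

**Permutation p.** The null severs the genotype–phenotype link: whole subject
genotype rows are permuted across subjects, keeping each subject's trajectory,
covariates and within-subject correlation intact, and the entire search is
rerun per permutation. The empirical p is the fraction of permuted minimized
AICs ≤ the observed one (ties count; the observed value is not added to the
denominator, matching the plain "percentage" definition — under the null this
is mildly anti-conservative at the third decimal, which the calibration test
bounds). A literal subject-block BMI permutation — reassigning whole
trajectories across subjects — is available via `scheme="bmi"`; it also
destroys the BMI–age and BMI–covariate structure, which is why it is not the
default. Default `n_perm` is 1,000; 10,000 is a flag away; the calibration
suites use 100–200.

Missing dosages are mean-imputed per SNP inside burden construction only (so
the score is defined for every subject); the scans drop missing pairwise.

## The synthetic cohort generator

The generator is the testbed for every downstream contract. Defaults encode
the study conditions: 658 subjects (308 male / 350 female), sex-specific birth
weight 3.47 / 3.33 (SD 0.52) kg, gestational age 39.8 (1.8) weeks, mean visit
counts 4.3 (childhood, ages 3–<18) and 4.5 (adulthood, 18–45), genotypes in
HWE at the panel MAFs. Visit counts are 1 + Poisson(mean − 1) (every subject
has ≥ 1 visit per stratum); visit ages are uniform within the stratum range
and independent across visits — the analyses condition on age, not survey
wave, so spacing structure is immaterial to what the tests check, but no test
should (and none does) depend on the age distribution's shape. BMI
trajectories follow the generative counterpart of the analysis model with
stratum-specific intercept and age slope chosen to match the cohort's printed
anthropometry (childhood ≈ 17.6 kg/m² near age 10; adulthood ≈ 27.7 near age
32): child intercept 13.1 + 0.45/yr, adult 19.6 + 0.25/yr, sex effect 0.3,
birth-weight effect 0.5 per kg, random intercept SD 2.0, random slope SD 0.12
per year (correlation 0.2), residual SD 1.5. Genetic effects default to zero;
tests inject additive betas, genotype-class pairs, per-year age interactions,
per-kg birth-weight interactions, and (off by default, since the null scan
expects none) a genotype → birth-weight path.

What the generator deliberately omits — and hence what passing tests do *not*
demonstrate about real data: linkage disequilibrium between panel SNPs,
secular/cohort time trends, visit-spacing structure, dropout and attrition,
measurement error in covariates, and population stratification.

## Power

Power for a predictor explaining a fraction R² of trait variance in n
subjects uses the noncentral chi-square: λ = n·R²/(1 − R²), power =
P(χ²_df(λ) > χ²_df critical at 1 − α). The headline design number (80% power
at R² = 0.023, n = 658, α = 0.05/23, df = 1) is the plain cross-sectional
calculation at the subject-level n; the ~4-fold observation inflation from
repeated measures is deliberately not folded in, but
`effective_sample_size(n, m, ICC)` exposes the standard adjustment for
exploration. `minimum_detectable_r2` inverts the power curve by bracketed
root-finding.

## Numerical choices and edge cases

* Optimizer: Nelder-Mead on log-Cholesky variance parameters, start
  Ψ = diag(1, 0.05) (intercept variance ≈ residual variance; small slope);
  warm starts inside the search. Public fits converge the deviance to ~1e-9;
  search candidate fits use 1e-6 (the AIC penalty unit is 2).
* Rank-deficient designs raise an error naming the collinear columns (QR with
  pivoting); a constant modifier in an interaction model is caught this way.
* Non-converged fits are recorded as missing in scans (excluded from FDR) and
  are unavailable candidates in the search.
* Monomorphic SNPs: skipped in scans with a warning; HWE test raises
  (undefined); in the search a constant burden is collinear and unavailable.
* A sample minor-allele frequency > 0.5 (minor/major flip in a small sample)
  is computed on the stored coding and logged, never re-polarized in QC.
* Degenerate noiseless data: the ML residual variance hits zero; the OLS path
  reports +inf log-likelihood with exact coefficients, the mixed path treats
  the fit as non-converged.
* All randomness flows from a single seed; pipeline outputs are byte-identical
  for identical config + seed.

## Test-suite problem sizes

Calibration and recovery suites run at fixed sizes chosen to make their Monte
Carlo error small against the tested bands: 1,000 null cohorts (n = 200,
3 childhood visits) for scan size; 1,000 mixture replicates (6 signals of 46)
for FDR control; 100 replicates at n = 658 for CI coverage; 100 searches at
n = 658 (5 causal SNPs of 23, β = 0.8 per allele — the clearly-detectable
single-SNP magnitude also used for the scan power checks, so the check probes
selection ordering rather than borderline power) for selection ordering; 100 outer × 200-permutation searches (n = 60,
6 SNPs, 2 visits) for permutation calibration. `scripts/acceptance.py` re-runs
the same studies at reduced replicate counts and records the sizes with each
number.

## Known limitations

* No REML mode, no non-Gaussian responses, no autoregressive residuals.
* The search refits the full model per candidate (no score approximation);
  correct but the dominant cost of permutation runs.
* Storey π₀ estimation is unstable at panel-sized families; BH is default.
* The burden is unweighted by construction; no exhaustive subset search or
  cross-validation of the selected model.
* VCF input is a convenience reader (dosage TSV is canonical); PLINK formats
  are unsupported.
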