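# bmilong

Longitudinal genetic association of repeated BMI measures: mixed-model
single-SNP scans with an FDR min-rule, SNP×age and SNP×birth-weight
interaction tests, and a heuristic forward search for the best joint-effect
allele-burden model under a per-SNP-penalized AIC with a permutation
empirical p-value.

## Who this is for

Genetic epidemiologists working with candidate-SNP panels and repeated
anthropometric measurements: cohorts where each subject contributes several
BMI observations at varying ages across childhood (age < 18) and adulthood
(≥ 18), and the questions are (i) which variants carry longitudinal main
effects per stratum, (ii) whether variant effects are modified by age or by
birth weight, and (iii) whether variants that are weak alone act jointly.
Because individual-level cohort data of this kind are typically not shareable,
the package ships a synthetic cohort generator that reproduces the assumed
statistical structure (658 subjects, ~4.3 childhood and ~4.5 adulthood visits,
genotypes in Hardy-Weinberg proportions at the 23-SNP panel MAFs), so the
entire pipeline is testable end to end.

## The model

Per-stratum longitudinal model, fitted by maximum likelihood:

    BMI_ij = β0 + β_a age_ij + β_s sex_i + β_w bw_i + g(SNP_i)
             + b0_i + b1_i age_ij + ε_ij,   (b0,b1) ~ N(0, G),  ε ~ N(0, σ²)

with g either additive (dosage, 1 df) or general (genotype factor, 2 df);
per-variant q = min(q_additive, q_general) with BH q-values computed per
(stratum × coding) family. Interactions add g×age or g×birth-weight products
(joint Wald test). The forward search grows a burden score S_i = Σ reference-
allele counts over selected SNPs, choosing at each step the (SNP, allele)
minimizing

    modified AIC = 2 (#SNPs + #non-SNP parameters) − 2 ln L,

accepting only strict decreases, and calibrates the minimized AIC against a
null in which subject genotype rows are permuted and the whole search rerun.
Design power uses the noncentral-χ² formulation with λ = nR²/(1−R²).

## Worked example

```python
from bmilong import (SimulationConfig, simulate_cohort, scan_main_effects,
                     summarize_variant_q, forward_search)

causal = ["rs2568958", "rs13107325", "rs7138803", "rs8050136", "rs29941"]
cfg = SimulationConfig(n_subjects=658, seed=5,
                       snp_effects={s: 0.5 for s in causal})  # kg/m2 per allele
cohort, phen = simulate_cohort(cfg)

scan = scan_main_effects(cohort, phen, "child")
print(summarize_variant_q(scan).nsmallest(3, "q_min").to_string(index=False))

est = forward_search(cohort, phen, "child")
print(est.steps_[["step", "snp_id", "ref_allele", "modified_aic",
                  "cum_r2_pct"]].head(5).to_string(index=False))
print(f"burden beta {est.burden_beta_:.3f} (SE {est.burden_se_:.3f})")
```

Output:

```
   snp_id stratum    q_min best_coding       p_best
  rs29941   child 0.000007    additive 2.964992e-07
rs2568958   child 0.000069     general 5.999950e-06
rs8050136   child 0.001692    additive 2.207498e-04
 step    snp_id ref_allele  modified_aic  cum_r2_pct
    1   rs29941          T  12038.857239    1.997982
    2 rs2568958          G  12023.984135    3.295003
    3 rs8050136          A  12010.382897    4.388849
burden beta 0.647 (SE 0.083)
```

The top scan hits are all simulated causal SNPs (q-values from the
additive/general min-rule), and the search selects three of them — risk
(minor) alleles as reference — before the per-SNP AIC penalty stops it: at
0.5 kg/m² per allele each SNP carries only ~1% of BMI variance, so the
greedy criterion keeps the strongest subset rather than all five. The
cumulative explained variance climbs step by step, and the burden CI
(0.65 ± 0.08) sits near the simulated per-allele effect.

A CLI mirrors the library: `bmilong simulate|qc|assoc|interact|search|power|
run-all` (see `bmilong --help`); `run-all` writes QC, scan, interaction and
search tables plus a variance-trace plot and a seed-stamped `summary.json`.

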