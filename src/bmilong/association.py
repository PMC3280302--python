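"""Single-SNP association scans of longitudinal BMI and of birth weight.

Each SNP is tested under two codings: additive (dosage 0/1/2 of the minor
allele, 1-df test) and general (genotype as a 3-level factor with the
major-allele homozygote as baseline, 2-df test). Longitudinal BMI scans use the
mixed model with age, sex and birth weight as fixed covariates and per-subject
random intercept + age slope; the birth-weight scan is an ordinary linear model
with gestational age and sex controlled. q-values are computed per
(stratum x coding) family and the per-variant q is the smaller of the two
codings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import fdr
from .lmm import MixedLMM, fit_lmm, wald_test
from .simulate import Cohort

log = logging.getLogger(__name__)

STRATA = ("child", "adult")


def stratum_table(cohort: Cohort, phenotype: pd.DataFrame,
                  stratum: str) -> pd.DataFrame:
    """Long observation table for one stratum with subject covariates merged in."""
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")
    sub = phenotype[phenotype["stratum"] == stratum]
    if sub.empty:
        raise ValueError(f"no observations in stratum {stratum!r}")
    covs = cohort.subjects.rename(columns={"id": "subject_id"})
    return sub.merge(covs, on="subject_id", how="inner")


def _snp_codings(dosage: np.ndarray):
    """Return the codings testable for a dosage vector (NaN = missing)."""
    called = dosage[~np.isnan(dosage)]
    classes = np.unique(called)
    if classes.size <= 1:
        return []
    codings = ["additive"]
    if classes.size == 3:
        codings.append("general")
    return codings


def _apply_family_q(results: pd.DataFrame, engine: str = "bh",
                    family_cols=("stratum", "coding")) -> pd.DataFrame:
    """Attach q-values computed within each (stratum x coding) family."""
    qfun = fdr.bh_qvalues if engine == "bh" else fdr.storey_qvalues
    results = results.copy()
    results["q"] = np.nan
    for _, idx in results.groupby(list(family_cols)).groups.items():
        p = results.loc[idx, "p"]
        ok = idx[p.notna()]
        if len(ok):
            results.loc[ok, "q"] = qfun(results.loc[ok, "p"].to_numpy())
    return results


def scan_main_effects(cohort: Cohort, phenotype: pd.DataFrame, stratum: str,
                      fdr_engine: str = "bh",
                      random_structure: str = "intercept_slope") -> pd.DataFrame:
    """Dual-coding mixed-model scan of one stratum.

    Returns one row per (SNP, coding) with effect estimates, Wald p, family
    q-value, and sample sizes. Monomorphic SNPs are skipped with a warning;
    SNPs missing a genotype class are tested under the additive coding only and
    flagged in ``note``. Subjects with a missing dosage are dropped pairwise.
    """
    base = stratum_table(cohort, phenotype, stratum)
    rows = []
    for snp in cohort.genotypes.columns:
        dose_by_subject = cohort.genotypes[snp].astype(float)
        data = base.assign(dosage=dose_by_subject.loc[base["subject_id"]].to_numpy())
        data = data[data["dosage"].notna()]
        codings = _snp_codings(data.drop_duplicates("subject_id")["dosage"].to_numpy())
        if not codings:
            log.warning("SNP %s monomorphic in stratum %s: skipped", snp, stratum)
            continue
        note = "" if "general" in codings else "missing_genotype_class"
        n_obs = len(data)
        n_subjects = data["subject_id"].nunique()
        for coding in codings:
            row = {"snp_id": snp, "stratum": stratum, "coding": coding,
                   "n_obs": n_obs, "n_subjects": n_subjects, "note": note,
                   "beta": np.nan, "se": np.nan, "beta_het": np.nan,
                   "se_het": np.nan, "beta_hom": np.nan, "se_hom": np.nan,
                   "p": np.nan}
            try:
                if coding == "additive":
                    fit = fit_lmm(data, ["dosage"],
                                  random_structure=random_structure)
                    if fit.converged_:
                        row["beta"] = fit.coef_[-1]
                        row["se"] = fit.se_[-1]
                        row["p"] = wald_test(fit, ["dosage"])
                else:
                    gdat = data.assign(het=(data["dosage"] == 1).astype(float),
                                       hom=(data["dosage"] == 2).astype(float))
                    fit = fit_lmm(gdat, ["het", "hom"],
                                  random_structure=random_structure)
                    if fit.converged_:
                        row["beta_het"], row["beta_hom"] = fit.coef_[-2:]
                        row["se_het"], row["se_hom"] = fit.se_[-2:]
                        row["p"] = wald_test(fit, ["het", "hom"])
                if not fit.converged_:
                    row["note"] = (row["note"] + ";nonconverged").lstrip(";")
            except np.linalg.LinAlgError:
                row["note"] = (row["note"] + ";singular_fit").lstrip(";")
            rows.append(row)
    results = pd.DataFrame(rows)
    return _apply_family_q(results, fdr_engine)


def summarize_variant_q(results: pd.DataFrame) -> pd.DataFrame:
    """Per-variant q: the smaller of the two coding families' q-values.

    Missing codings (monomorphic class, non-convergence) contribute nothing;
    a variant with no valid coding is absent from the summary.
    """
    valid = results[results["q"].notna()]
    if valid.empty:
        return pd.DataFrame(columns=["snp_id", "stratum", "q_min", "best_coding"])
    idx = valid.groupby(["snp_id", "stratum"])["q"].idxmin()
    out = valid.loc[idx, ["snp_id", "stratum", "q", "coding", "p"]].rename(
        columns={"q": "q_min", "coding": "best_coding", "p": "p_best"})
    return out.reset_index(drop=True)


def genotype_effects_report(fit: MixedLMM, minor_allele: str,
                            major_allele: str) -> dict:
    """Re-express general-model genotype effects against the lower-BMI homozygote.

    The model is fitted with the major-allele homozygote as baseline; for
    reporting, the baseline is switched (if needed) to whichever homozygote has
    the lower adjusted mean, and the heterozygote and remaining homozygote are
    expressed relative to it.
    """
    for term in ("het", "hom"):
        if term not in fit.feature_names_:
            raise KeyError("general-coding fit with 'het'/'hom' terms required")
    b_het = float(fit.coef_[fit.feature_names_.index("het")])
    b_hom = float(fit.coef_[fit.feature_names_.index("hom")])
    het_label = minor_allele + major_allele
    major_homo = major_allele * 2
    minor_homo = minor_allele * 2
    if b_hom >= 0:
        return {"baseline_genotype": major_homo,
                "effects": [(het_label, b_het), (minor_homo, b_hom)]}
    return {"baseline_genotype": minor_homo,
            "effects": [(het_label, b_het - b_hom), (major_homo, -b_hom)]}


def scan_birth_weight(cohort: Cohort, fdr_engine: str = "bh") -> pd.DataFrame:
    """Cross-sectional scan: birth_weight ~ genotype + gestational_age + sex.

    Ordinary linear model per SNP under both codings, FDR-adjusted within each
    coding family. Fits with fewer than 10 residual degrees of freedom are
    flagged ``unreliable_df``.
    """
    subs = cohort.subjects
    rows = []
    for snp in cohort.genotypes.columns:
        dosage = cohort.genotypes[snp].astype(float).loc[subs["id"]].to_numpy()
        keep = ~np.isnan(dosage)
        d = dosage[keep]
        codings = _snp_codings(d)
        if not codings:
            log.warning("SNP %s monomorphic: skipped in birth-weight scan", snp)
            continue
        y = subs.loc[keep, "birth_weight"].to_numpy(dtype=float)
        base = np.column_stack([
            np.ones(keep.sum()),
            subs.loc[keep, "gestational_age"].to_numpy(dtype=float),
            subs.loc[keep, "sex"].to_numpy(dtype=float),
        ])
        note = "" if "general" in codings else "missing_genotype_class"
        for coding in codings:
            if coding == "additive":
                X = np.column_stack([base, d])
                gidx = [3]
            else:
                X = np.column_stack([base, (d == 1).astype(float),
                                     (d == 2).astype(float)])
                gidx = [3, 4]
            res = sm.OLS(y, X).fit()
            bet = res.params[gidx]
            cov = np.asarray(res.cov_params())[np.ix_(gidx, gidx)]
            from scipy import stats as _st
            stat = float(bet @ np.linalg.solve(cov, bet))
            p = float(_st.chi2.sf(stat, df=len(gidx)))
            this_note = note
            if res.df_resid < 10:
                this_note = (this_note + ";unreliable_df").lstrip(";")
            row = {"snp_id": snp, "stratum": "birthweight", "coding": coding,
                   "n_obs": int(keep.sum()), "n_subjects": int(keep.sum()),
                   "note": this_note, "beta": np.nan, "se": np.nan,
                   "beta_het": np.nan, "se_het": np.nan, "beta_hom": np.nan,
                   "se_hom": np.nan, "p": p}
            if coding == "additive":
                row["beta"], row["se"] = float(res.params[3]), float(res.bse[3])
            else:
                row["beta_het"], row["se_het"] = float(res.params[3]), float(res.bse[3])
                row["beta_hom"], row["se_hom"] = float(res.params[4]), float(res.bse[4])
            rows.append(row)
    results = pd.DataFrame(rows)
    return _apply_family_q(results, fdr_engine)
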