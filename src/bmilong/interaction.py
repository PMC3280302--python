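"""SNP-by-age and SNP-by-birth-weight interaction tests in the mixed model.

The main-effect longitudinal model is augmented with genotype x modifier
product terms (two under the general coding, one under the additive coding) and
the products are tested jointly by Wald chi-square. Under the general coding
the reported beta1/beta2 are the per-unit effect changes of the heterozygote
and of the reference-allele homozygote against the major-homozygote baseline —
per year for the age modifier, per kilogram for birth weight. All main effects
stay in the model; ages are used raw (uncentered) so betas read as "per one-year
increase in age".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .association import _apply_family_q, _snp_codings, stratum_table
from .lmm import fit_lmm, wald_test
from .simulate import Cohort

log = logging.getLogger(__name__)

MODIFIERS = ("age", "birth_weight")


def test_interaction(cohort: Cohort, phenotype: pd.DataFrame, snp: str,
                     modifier: str, stratum: str, coding: str = "general",
                     random_structure: str = "intercept_slope") -> dict:
    """Joint Wald test of genotype x modifier product terms for one SNP.

    Returns a record with the reference (minor) allele, beta1/beta2 (general
    coding) or the single additive interaction beta, and the joint p-value.
    Raises the engine's rank error (naming the collinear columns) when the
    modifier is constant, since the products then duplicate the main effects.
    """
    if modifier not in MODIFIERS:
        raise ValueError(f"modifier must be one of {MODIFIERS}")
    data = stratum_table(cohort, phenotype, stratum)
    dose = cohort.genotypes[snp].astype(float).loc[data["subject_id"]].to_numpy()
    data = data.assign(dosage=dose)
    data = data[data["dosage"].notna()]
    codings = _snp_codings(data.drop_duplicates("subject_id")["dosage"].to_numpy())
    if not codings:
        raise ValueError(f"SNP {snp} monomorphic in stratum {stratum}")
    note = ""
    if coding == "general" and "general" not in codings:
        coding = "additive"
        note = "missing_genotype_class"

    mod = data[modifier].to_numpy(dtype=float)
    rec = {"snp_id": snp, "stratum": stratum, "modifier": modifier,
           "coding": coding, "note": note, "beta1": np.nan, "beta2": np.nan,
           "se1": np.nan, "se2": np.nan, "p": np.nan,
           "n_obs": len(data), "n_subjects": data["subject_id"].nunique()}
    if coding == "general":
        d = data["dosage"].to_numpy()
        gdat = data.assign(
            het=(d == 1).astype(float), hom=(d == 2).astype(float),
            het_x_mod=(d == 1) * mod, hom_x_mod=(d == 2) * mod,
        )
        fit = fit_lmm(gdat, ["het", "hom", "het_x_mod", "hom_x_mod"],
                      random_structure=random_structure)
        terms = ["het_x_mod", "hom_x_mod"]
        rec["beta1"] = fit.coef_[fit.feature_names_.index("het_x_mod")]
        rec["beta2"] = fit.coef_[fit.feature_names_.index("hom_x_mod")]
        rec["se1"] = fit.se_[fit.feature_names_.index("het_x_mod")]
        rec["se2"] = fit.se_[fit.feature_names_.index("hom_x_mod")]
    else:
        gdat = data.assign(dos_x_mod=data["dosage"].to_numpy() * mod)
        fit = fit_lmm(gdat, ["dosage", "dos_x_mod"],
                      random_structure=random_structure)
        terms = ["dos_x_mod"]
        rec["beta1"] = fit.coef_[fit.feature_names_.index("dos_x_mod")]
        rec["se1"] = fit.se_[fit.feature_names_.index("dos_x_mod")]
    if fit.converged_:
        rec["p"] = wald_test(fit, terms)
    else:
        rec["note"] = (rec["note"] + ";nonconverged").lstrip(";")
    rec["reference_allele"] = _minor_allele_label(cohort, snp)
    return rec


def _minor_allele_label(cohort: Cohort, snp: str) -> str:
    from .panel import default_panel
    try:
        return default_panel().alleles(snp)[0]
    except KeyError:
        return "minor"


def scan_interactions(cohort: Cohort, phenotype: pd.DataFrame, stratum: str,
                      modifier: str, fdr_engine: str = "bh",
                      random_structure: str = "intercept_slope") -> pd.DataFrame:
    """Panel-wide interaction scan, both codings, with family q-values.

    q-values are computed within each (stratum x modifier x coding) family;
    combine across codings with :func:`bmilong.association.summarize_variant_q`.
    An empty panel returns an empty table.
    """
    rows = []
    for snp in cohort.genotypes.columns:
        for coding in ("additive", "general"):
            try:
                rec = test_interaction(cohort, phenotype, snp, modifier,
                                       stratum, coding=coding,
                                       random_structure=random_structure)
            except ValueError as exc:
                log.warning("interaction scan skips %s (%s): %s", snp, coding, exc)
                continue
            if coding == "general" and rec["coding"] == "additive":
                continue  # degenerate fallback already covered by additive row
            rows.append(rec)
    cols = ["snp_id", "stratum", "modifier", "coding", "reference_allele",
            "beta1", "beta2", "se1", "se2", "p", "q", "n_obs", "n_subjects",
            "note"]
    if not rows:
        return pd.DataFrame(columns=cols)
    results = pd.DataFrame(rows)
    results = _apply_family_q(results, fdr_engine,
                              family_cols=("stratum", "modifier", "coding"))
    return results[cols]
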