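"""File formats, validation, and the end-to-end pipeline runner.

Canonical on-disk formats are plain tab-separated tables (the data scale is 23
SNPs x 658 subjects, so nothing heavier is warranted):

* ``subjects.tsv`` — id, sex (1 = male), birth_weight (kg), gestational_age (weeks)
* ``genotypes.tsv`` — id column + one minor-allele dosage column per SNP (0/1/2/NA)
* ``phenotypes.tsv`` — subject_id, age (years), bmi (kg/m2)
* ``truth.json`` — generating parameters of a simulated cohort

Writers prepend a ``#`` comment line naming the units; readers skip comments.
VCF is accepted as a convenience genotype source only (dosages are re-polarized
to count the panel's minor allele).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genostats import qc_report
from .panel import SnpPanel
from .simulate import Cohort, SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)

_UNITS_GENO = "# units: dosage=minor-allele copies (0/1/2, NA=missing)"
_UNITS_SUBJ = "# units: sex=1 male/0 female, birth_weight=kg, gestational_age=weeks"
_UNITS_PHEN = "# units: age=years, bmi=kg/m2"


class GenotypeParseError(ValueError):
    """A genotype cell is not a valid dosage; carries row/column coordinates."""


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    """Write a subjects x SNPs dosage matrix (index = subject id)."""
    with open(path, "w") as fh:
        fh.write(_UNITS_GENO + "\n")
        genotypes.rename_axis("id").to_csv(fh, sep="\t", na_rep="NA",
                                           float_format="%.0f")


def read_genotypes(path) -> pd.DataFrame:
    """Read and validate a dosage TSV; returns the matrix indexed by subject id.

    Cells must be 0, 1, 2 or NA; a bad cell raises
    :class:`GenotypeParseError` naming its subject row and SNP column.
    Duplicated subject ids are an error.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if raw.columns[0] != "id":
        raise GenotypeParseError(
            f"first column must be 'id', got {raw.columns[0]!r}")
    if raw["id"].duplicated().any():
        dup = raw.loc[raw["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicated subject id(s): {dup}")
    mat = raw.set_index("id")
    values = np.full(mat.shape, np.nan)
    for j, snp in enumerate(mat.columns):
        col = mat[snp]
        for i, cell in enumerate(col):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or cell in ("NA", "", "nan"):
                continue
            if cell not in ("0", "1", "2"):
                raise GenotypeParseError(
                    f"invalid dosage {cell!r} at subject {mat.index[i]!r}, "
                    f"SNP {snp!r}")
            values[i, j] = float(cell)
    out = pd.DataFrame(values, index=mat.index, columns=mat.columns)
    log.info("read genotypes: %d subjects x %d SNPs", *out.shape)
    return out


def read_genotypes_vcf(path, panel: SnpPanel) -> pd.DataFrame:
    """Read genotypes from a VCF, counting the panel's minor allele.

    When the VCF's REF allele is the panel minor allele, ALT dosages are
    flipped (2 - d) so the returned matrix always counts minor-allele copies;
    each flip is logged. Records whose alleles match neither panel orientation
    are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = {}
    panel_idx = panel.table.set_index("snp_id")
    for rec in vcf:
        rid = rec.ID
        if rid not in panel_idx.index:
            continue
        minor = panel_idx.loc[rid, "minor_allele"]
        major = panel_idx.loc[rid, "major_allele"]
        alt = rec.ALT[0] if rec.ALT else None
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        alt_dos = np.array([0.0, 1.0, np.nan, 2.0])[rec.gt_types]
        if rec.REF == major and alt == minor:
            cols[rid] = alt_dos
        elif rec.REF == minor and alt == major:
            cols[rid] = 2.0 - alt_dos
            log.info("VCF REF/ALT swapped vs panel for %s: dosages flipped", rid)
        else:
            log.warning("VCF alleles %s/%s for %s match neither panel "
                        "orientation; skipped", rec.REF, alt, rid)
    return pd.DataFrame(cols, index=pd.Index(samples, name="id"))


def write_subjects(subjects: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_SUBJ + "\n")
        subjects.to_csv(fh, sep="\t", index=False)


def read_subjects(path) -> pd.DataFrame:
    subs = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "sex", "birth_weight", "gestational_age"}
    missing = required - set(subs.columns)
    if missing:
        raise ValueError(f"subjects table missing columns: {sorted(missing)}")
    return subs


def write_phenotypes(phenotype: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_PHEN + "\n")
        phenotype.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path, known_ids=None) -> pd.DataFrame:
    """Read long-format (subject_id, age, bmi) records and derive the stratum.

    The stratum is childhood for age < 18 years and adulthood for age >= 18.
    Ages outside [0, 120] or non-positive BMIs are rejected; subject ids not in
    ``known_ids`` (when given) raise an error listing them.
    """
    phen = pd.read_csv(path, sep="\t", comment="#")
    required = {"subject_id", "age", "bmi"}
    missing = required - set(phen.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    age = phen["age"].astype(float)
    bmi = phen["bmi"].astype(float)
    bad = phen[(age < 0) | (age > 120) | (bmi <= 0) | age.isna() | bmi.isna()]
    if len(bad):
        raise ValueError(
            f"invalid age/BMI values in rows {bad.index.tolist()[:10]}")
    if known_ids is not None:
        unknown = sorted(set(phen["subject_id"]) - set(known_ids))
        if unknown:
            raise ValueError(f"unknown subject ids in phenotypes: {unknown}")
    phen = phen.assign(stratum=np.where(age < 18.0, "child", "adult"))
    return phen[["subject_id", "age", "bmi", "stratum"]]


def write_cohort(cohort: Cohort, phenotype: pd.DataFrame, out_dir) -> None:
    """Write subjects.tsv, genotypes.tsv, phenotypes.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_subjects(cohort.subjects, out / "subjects.tsv")
    write_genotypes(cohort.genotypes, out / "genotypes.tsv")
    write_phenotypes(phenotype, out / "phenotypes.tsv")
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2))


def read_cohort(in_dir) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    subjects = read_subjects(src / "subjects.tsv")
    genotypes = read_genotypes(src / "genotypes.tsv")
    truth_path = src / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    phen = read_phenotypes(src / "phenotypes.tsv", known_ids=subjects["id"])
    return Cohort(subjects=subjects, genotypes=genotypes, truth=truth), phen


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    Either ``simulation`` (a :class:`SimulationConfig`) or the three input
    table paths must be provided. ``seed`` drives every random stage (the
    permutation seed is derived from it deterministically).
    """

    out_dir: str = "bmilong_out"
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    subjects_path: str | None = None
    phenotypes_path: str | None = None
    strata: tuple = ("child", "adult")
    fdr_engine: str = "bh"
    n_perm: int = 200
    run_search: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            paths = [self.genotypes_path, self.subjects_path,
                     self.phenotypes_path]
            if any(p is None for p in paths):
                raise ValueError("provide a simulation config or all three "
                                 "input table paths")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.fdr_engine not in ("bh", "storey"):
            raise ValueError("fdr_engine must be 'bh' or 'storey'")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # where results land is not part of what they are
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """QC -> association scans -> interaction scans -> joint search -> power.

    Every artifact is stamped with the seed, config hash and package version;
    identical config + seed reproduces identical outputs. Stage failures abort
    with the stage name.
    """
    from . import association, interaction, power
    from .search import ForwardBurdenSearch, plot_variance_trace

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash(),
             "version": __version__}
    summary: dict = {"stamp": stamp, "stages": {}}
    stage = "load"
    try:
        t0 = time.time()
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort, phen = simulate_cohort(sim)
            write_cohort(cohort, phen, out / "cohort")
        else:
            subjects = read_subjects(config.subjects_path)
            genotypes = read_genotypes(config.genotypes_path)
            phen = read_phenotypes(config.phenotypes_path,
                                   known_ids=subjects["id"])
            cohort = Cohort(subjects=subjects, genotypes=genotypes, truth={})
        log.info("stage %s done in %.2fs", stage, time.time() - t0)
        summary["stages"][stage] = {"n_subjects": len(cohort.subjects),
                                    "n_obs": len(phen)}

        stage = "qc"
        t0 = time.time()
        qc = qc_report(cohort.genotypes)
        _write_table(qc, out / "qc.tsv", "maf/het are allele fractions")
        log.info("stage %s done in %.2fs", stage, time.time() - t0)
        summary["stages"][stage] = {"n_snps": len(qc)}

        stage = "association"
        t0 = time.time()
        scans = []
        for stratum in config.strata:
            scans.append(association.scan_main_effects(
                cohort, phen, stratum, fdr_engine=config.fdr_engine))
        scans.append(association.scan_birth_weight(
            cohort, fdr_engine=config.fdr_engine))
        assoc = pd.concat(scans, ignore_index=True)
        _write_table(assoc, out / "association.tsv",
                     "beta=kg/m2 per allele (bmi) or kg per allele (birthweight)")
        _write_table(association.summarize_variant_q(assoc),
                     out / "association_variant_q.tsv", "min-q rule per variant")
        log.info("stage %s done in %.2fs", stage, time.time() - t0)
        summary["stages"][stage] = {"n_tests": int(assoc["p"].notna().sum())}

        stage = "interaction"
        t0 = time.time()
        inters = []
        for stratum in config.strata:
            for modifier in ("age", "birth_weight"):
                inters.append(interaction.scan_interactions(
                    cohort, phen, stratum, modifier,
                    fdr_engine=config.fdr_engine))
        inter = pd.concat(inters, ignore_index=True)
        _write_table(inter, out / "interactions.tsv",
                     "beta1/beta2 = kg/m2 per year (age) or per kg (birth weight)")
        log.info("stage %s done in %.2fs", stage, time.time() - t0)
        summary["stages"][stage] = {"n_tests": int(inter["p"].notna().sum())}

        if config.run_search:
            stage = "search"
            t0 = time.time()
            summary["search"] = {}
            for i, stratum in enumerate(config.strata):
                est = ForwardBurdenSearch(
                    n_perm=config.n_perm,
                    random_state=(config.seed + 7919 * (i + 1)) % (2 ** 31),
                ).fit(cohort, phen, stratum=stratum)
                _write_table(est.steps_, out / f"search_{stratum}.tsv",
                             "modified_aic unitless, r2 columns in percent")
                plot_variance_trace(est, out / f"search_{stratum}.png")
                summary["search"][stratum] = {
                    "n_selected": len(est.steps_),
                    "min_aic": est.min_aic_,
                    "baseline_aic": est.baseline_aic_,
                    "burden_beta": est.burden_beta_,
                    "burden_se": est.burden_se_,
                    "empirical_p": est.empirical_p_,
                    "n_perm": config.n_perm,
                }
            log.info("stage %s done in %.2fs", stage, time.time() - t0)
            summary["stages"][stage] = {"n_strata": len(config.strata)}

        stage = "power"
        alpha = power.bonferroni_threshold(0.05, len(cohort.genotypes.columns))
        summary["power"] = {
            "per_test_alpha": alpha,
            "power_r2_0.023": power.power_variance_explained(
                len(cohort.subjects), 0.023, alpha, df=1),
            "min_detectable_r2_80pct": power.minimum_detectable_r2(
                len(cohort.subjects), alpha, 0.80, df=1),
        }
    except Exception as exc:
        log.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
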