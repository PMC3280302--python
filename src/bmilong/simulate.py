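"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the downstream analyses assume: 658 subjects
genotyped at the 23-SNP candidate panel (independent SNPs in Hardy-Weinberg
proportions at the panel MAFs), sex-specific birth weights, gestational ages,
and repeated BMI measurements over a childhood (ages 3 to <18) and an adulthood
(18-45) stratum, with on average ~4.3 childhood and ~4.5 adulthood visits per
subject. BMI trajectories follow the generative counterpart of the analysis
model: stratum-specific fixed intercept and age slope, sex and birth-weight
effects, configurable SNP main effects (additive dosage or genotype-class
pairs), SNP-by-age and SNP-by-birth-weight interactions, a correlated
per-subject random intercept and age slope, and iid Gaussian residuals.

The generator intentionally omits LD between SNPs, within-subject visit
spacing, secular trends, and dropout; analyses condition on age, not on survey
wave, so none of these affect the contracts under test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import SnpPanel, default_panel

__all__ = ["SimulationConfig", "Cohort", "simulate_genotypes",
           "simulate_subjects", "simulate_trajectories", "simulate_cohort"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 658 subjects (308 male, 350
    female), sex-specific birth weight means 3.47/3.33 kg (SD 0.52), gestational
    age 39.8 (1.8) weeks, mean visit counts 4.3 (childhood) and 4.5 (adulthood),
    and BMI trajectory parameters chosen so that simulated means match the
    cohort's printed anthropometry (childhood BMI ~17.6 kg/m2 near age 10,
    adulthood BMI ~27.7 near age 32).

    Genetic effects default to zero (a null cohort); tests inject effects via
    ``snp_effects`` (scalar = kg/m2 per minor allele; pair = heterozygote and
    minor-homozygote offsets), ``age_interactions`` (per year) and
    ``bw_interactions`` (per kg). ``bw_snp_effects`` (kg per allele) provides
    the optional genotype-to-birth-weight path, off by default.
    """

    n_subjects: int = 658
    snp_panel: SnpPanel | None = None
    sex_ratio: float = 308 / 658          # fraction male
    birth_weight_mean_male: float = 3.47  # kg
    birth_weight_mean_female: float = 3.33
    birth_weight_sd: float = 0.52
    gestational_age_mean: float = 39.8    # weeks
    gestational_age_sd: float = 1.8
    visits_child_mean: float = 4.3
    visits_adult_mean: float = 4.5
    child_age_range: tuple[float, float] = (3.0, 18.0)   # [min, 18)
    adult_age_range: tuple[float, float] = (18.0, 45.0)
    baseline_bmi: dict = field(default_factory=lambda: {"child": 13.1, "adult": 19.6})
    age_slope: dict = field(default_factory=lambda: {"child": 0.45, "adult": 0.25})
    sex_effect: float = 0.3               # kg/m2, male minus female
    bw_effect: float = 0.5                # kg/m2 per kg birth weight
    random_intercept_sd: float = 2.0      # kg/m2
    random_slope_sd: float = 0.12         # kg/m2 per year
    random_corr: float = 0.2
    residual_sd: float = 1.5              # kg/m2
    snp_effects: dict = field(default_factory=dict)
    age_interactions: dict = field(default_factory=dict)
    bw_interactions: dict = field(default_factory=dict)
    bw_snp_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.snp_panel is None:
            self.snp_panel = default_panel()
        for name in ("birth_weight_sd", "gestational_age_sd",
                     "random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.random_corr) > 1:
            raise ValueError("|random_corr| must be <= 1")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.visits_child_mean < 1 or self.visits_adult_mean < 1:
            raise ValueError("mean visit counts must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.child_age_range[1] <= 18.0 <= self.adult_age_range[0]):
            raise ValueError("age ranges must be disjoint at 18 years")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snp_panel"] = self.snp_panel.table.to_dict(orient="list")
        d["child_age_range"] = list(self.child_age_range)
        d["adult_age_range"] = list(self.adult_age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "snp_panel" in d and d["snp_panel"] is not None:
            d["snp_panel"] = SnpPanel(pd.DataFrame(d["snp_panel"]))
        for key in ("child_age_range", "adult_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class Cohort:
    """Simulated subjects, their genotypes, and the generating parameters.

    ``subjects`` has columns id, sex (1 = male), birth_weight (kg),
    gestational_age (weeks); ``genotypes`` is a subjects x SNPs minor-allele
    dosage matrix indexed by subject id; ``truth`` records the parameters used
    so recovery tests can compare estimates against them.
    """

    subjects: pd.DataFrame
    genotypes: pd.DataFrame
    truth: dict

    def __post_init__(self):
        g = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")
        if self.subjects["id"].duplicated().any():
            raise ValueError("duplicate subject ids")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(panel: SnpPanel, n: int, seed=0) -> pd.DataFrame:
    """Independent HWE genotypes: dosage ~ Binomial(2, maf) per subject per SNP."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mafs = panel.mafs.to_numpy()
    if ((mafs < 0) | (mafs > 0.5)).any():
        raise ValueError("MAFs must lie in [0, 0.5]")
    rng = _rng(seed)
    g = rng.binomial(2, mafs, size=(n, len(mafs)))
    return pd.DataFrame(g, columns=panel.snp_ids)


def simulate_subjects(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Subject-level covariates: sex, birth weight (kg), gestational age (weeks)."""
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_subjects
    sex = (rng.random(n) < config.sex_ratio).astype(int)  # 1 = male
    bw_mean = np.where(sex == 1, config.birth_weight_mean_male,
                       config.birth_weight_mean_female)
    birth_weight = rng.normal(bw_mean, config.birth_weight_sd)
    gest_age = rng.normal(config.gestational_age_mean, config.gestational_age_sd, n)
    return pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "sex": sex,
        "birth_weight": birth_weight,
        "gestational_age": gest_age,
    })


def _effect_values(effect, dosage: np.ndarray) -> np.ndarray:
    """Genetic contribution per subject: scalar = additive beta per allele,
    (het, hom) pair = genotype-class offsets against the major homozygote."""
    if np.isscalar(effect):
        return float(effect) * dosage
    b_het, b_hom = effect
    return np.where(dosage == 1, float(b_het),
                    np.where(dosage == 2, float(b_hom), 0.0))


def _shifted_poisson(rng, mean: float, n: int) -> np.ndarray:
    """Visit counts >= 1 with the stated mean: 1 + Poisson(mean - 1)."""
    return 1 + rng.poisson(mean - 1.0, size=n)


def simulate_trajectories(cohort: Cohort, config: SimulationConfig,
                          seed=None) -> pd.DataFrame:
    """Repeated (subject, age, BMI) records for both strata.

    BMI = baseline_s + slope_s*age + sex_effect*sex + bw_effect*bw
          + genetic mains + age/birth-weight interaction terms
          + b0_i + b1_i*age + eps,   (b0, b1) bivariate normal, eps iid normal.
    """
    rng = _rng(config.seed if seed is None else seed)
    subs = cohort.subjects
    n = len(subs)
    geno = cohort.genotypes.loc[subs["id"]].to_numpy(dtype=float)
    snp_ids = list(cohort.genotypes.columns)

    cov_re = np.array([
        [config.random_intercept_sd ** 2,
         config.random_corr * config.random_intercept_sd * config.random_slope_sd],
        [config.random_corr * config.random_intercept_sd * config.random_slope_sd,
         config.random_slope_sd ** 2],
    ])
    b = rng.multivariate_normal(np.zeros(2), cov_re, size=n, method="svd")

    # per-subject constant genetic pieces
    main = np.zeros(n)
    slope_mod = np.zeros(n)   # extra kg/m2 per year from age interactions
    for snp, eff in config.snp_effects.items():
        main += _effect_values(eff, geno[:, snp_ids.index(snp)])
    for snp, eff in config.age_interactions.items():
        slope_mod += _effect_values(eff, geno[:, snp_ids.index(snp)])
    bw = subs["birth_weight"].to_numpy()
    for snp, eff in config.bw_interactions.items():
        main += _effect_values(eff, geno[:, snp_ids.index(snp)]) * bw

    records = []
    strata = [
        ("child", config.visits_child_mean, config.child_age_range),
        ("adult", config.visits_adult_mean, config.adult_age_range),
    ]
    sex = subs["sex"].to_numpy()
    ids = subs["id"].to_numpy()
    for stratum, mean_visits, (lo, hi) in strata:
        counts = _shifted_poisson(rng, mean_visits, n)
        for i in range(n):
            ages = rng.uniform(lo, hi, size=counts[i])
            eps = rng.normal(0.0, config.residual_sd, size=counts[i])
            bmi = (config.baseline_bmi[stratum]
                   + config.age_slope[stratum] * ages
                   + config.sex_effect * sex[i]
                   + config.bw_effect * bw[i]
                   + main[i] + slope_mod[i] * ages
                   + b[i, 0] + b[i, 1] * ages
                   + eps)
            for a, v in zip(ages, bmi):
                records.append((ids[i], float(a), float(v), stratum))
    phen = pd.DataFrame(records, columns=["subject_id", "age", "bmi", "stratum"])
    return phen.sort_values(["subject_id", "stratum", "age"],
                            kind="stable").reset_index(drop=True)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Compose genotypes, subjects and trajectories; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    subjects = simulate_subjects(config, seed=rng)
    genotypes = simulate_genotypes(config.snp_panel, config.n_subjects, seed=rng)
    genotypes.index = subjects["id"]

    if config.bw_snp_effects:
        snp_ids = list(genotypes.columns)
        shift = np.zeros(config.n_subjects)
        for snp, eff in config.bw_snp_effects.items():
            shift += _effect_values(eff, genotypes.iloc[:, snp_ids.index(snp)].to_numpy(float))
        subjects = subjects.assign(birth_weight=subjects["birth_weight"] + shift)

    truth = {
        "snp_effects": {k: (list(v) if not np.isscalar(v) else float(v))
                        for k, v in config.snp_effects.items()},
        "age_interactions": {k: (list(v) if not np.isscalar(v) else float(v))
                             for k, v in config.age_interactions.items()},
        "bw_interactions": {k: (list(v) if not np.isscalar(v) else float(v))
                            for k, v in config.bw_interactions.items()},
        "bw_snp_effects": {k: (list(v) if not np.isscalar(v) else float(v))
                           for k, v in config.bw_snp_effects.items()},
        "baseline_bmi": dict(config.baseline_bmi),
        "age_slope": dict(config.age_slope),
        "sex_effect": config.sex_effect,
        "bw_effect": config.bw_effect,
        "random_intercept_sd": config.random_intercept_sd,
        "random_slope_sd": config.random_slope_sd,
        "random_corr": config.random_corr,
        "residual_sd": config.residual_sd,
        "seed": config.seed,
    }
    json.dumps(truth)  # guarantee the record round-trips through JSON
    cohort = Cohort(subjects=subjects, genotypes=genotypes, truth=truth)
    phenotype = simulate_trajectories(cohort, config, seed=rng)
    return cohort, phenotype
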