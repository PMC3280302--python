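"""Synthetic cohort generator: distributional targets and determinism."""

import json

import numpy as np
import pandas as pd
import pytest

from bmilong.panel import SnpPanel, default_panel
from bmilong.simulate import (SimulationConfig, simulate_cohort,
                              simulate_genotypes, simulate_subjects,
                              simulate_trajectories)


def test_default_panel_has_23_snps():
    panel = default_panel()
    assert len(panel) == 23
    assert panel.mafs.between(0.0, 0.5).all()


def test_genotypes_degenerate_maf_zero():
    panel = SnpPanel(pd.DataFrame({
        "snp_id": ["s1"], "gene": ["G"], "chr": ["1"], "strand": ["+"],
        "position": [1], "minor_allele": ["A"], "major_allele": ["G"],
        "maf": [0.0]}))
    g = simulate_genotypes(panel, 50, seed=0)
    assert (g["s1"] == 0).all()


def test_genotypes_binomial_law_at_half():
    panel = default_panel().subset(["rs1121980"])
    panel.table.loc[0, "maf"] = 0.5
    g = simulate_genotypes(panel, 10_000, seed=1).iloc[:, 0]
    assert abs(g.mean() / 2 - 0.5) < 0.015
    props = g.value_counts(normalize=True)
    assert props[1] == pytest.approx(0.5, abs=0.03)
    assert props[0] == pytest.approx(0.25, abs=0.03)


def test_genotypes_deterministic():
    panel = default_panel()
    a = simulate_genotypes(panel, 100, seed=9)
    b = simulate_genotypes(panel, 100, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_subjects_birth_weight_means():
    cfg = SimulationConfig(n_subjects=100_000, seed=3)
    subs = simulate_subjects(cfg)
    male = subs[subs.sex == 1]
    assert male["birth_weight"].mean() == pytest.approx(3.47, abs=0.01)
    assert subs[subs.sex == 0]["birth_weight"].mean() == pytest.approx(3.33, abs=0.01)


def test_subjects_degenerate_options():
    cfg = SimulationConfig(n_subjects=200, seed=4, birth_weight_sd=0.0,
                           sex_ratio=1.0)
    subs = simulate_subjects(cfg)
    assert (subs.sex == 1).all()
    assert (subs.birth_weight == 3.47).all()


def _noiseless_config(**kw):
    return SimulationConfig(
        n_subjects=60, seed=5, sex_effect=0.0, bw_effect=0.0,
        random_intercept_sd=0.0, random_slope_sd=0.0, random_corr=0.0,
        residual_sd=0.0, baseline_bmi={"child": 17.6, "adult": 17.6},
        age_slope={"child": 0.0, "adult": 0.0}, **kw)


def test_trajectories_noiseless_constant():
    cohort, phen = simulate_cohort(_noiseless_config())
    child = phen[phen.stratum == "child"]
    assert np.allclose(child["bmi"], 17.6)


def test_trajectories_exact_additive_effect():
    cfg = _noiseless_config(snp_effects={"rs7138803": 0.5})
    cohort, phen = simulate_cohort(cfg)
    merged = phen.merge(cohort.genotypes["rs7138803"].rename("dos"),
                        left_on="subject_id", right_index=True)
    assert np.allclose(merged["bmi"], 17.6 + 0.5 * merged["dos"])


def test_trajectories_random_slope_variance():
    """With only a random slope, Var(BMI | age) = slope_sd^2 * age^2."""
    cfg = SimulationConfig(
        n_subjects=4000, seed=6, sex_effect=0.0, bw_effect=0.0,
        random_intercept_sd=0.0, random_slope_sd=0.3, random_corr=0.0,
        residual_sd=0.0, baseline_bmi={"child": 17.0, "adult": 17.0},
        age_slope={"child": 0.0, "adult": 0.0}, visits_child_mean=1.0,
        visits_adult_mean=1.0)
    cohort, phen = simulate_cohort(cfg)
    child = phen[phen.stratum == "child"]
    implied_slope = (child["bmi"] - 17.0) / child["age"]
    assert implied_slope.std() == pytest.approx(0.3, rel=0.05)


def test_stratum_age_ranges(null_cohort):
    _, phen = null_cohort
    child = phen[phen.stratum == "child"]
    adult = phen[phen.stratum == "adult"]
    assert ((child.age >= 3.0) & (child.age < 18.0)).all()
    assert ((adult.age >= 18.0) & (adult.age <= 45.0)).all()


def test_mean_visit_counts_match_defaults():
    counts = []
    for seed in range(5):
        cfg = SimulationConfig(n_subjects=658, seed=seed)
        cohort, phen = simulate_cohort(cfg)
        child = phen[phen.stratum == "child"]
        counts.append(len(child) / cfg.n_subjects)
    assert np.mean(counts) == pytest.approx(4.3, abs=0.2)


def test_simulate_cohort_deterministic():
    cfg = SimulationConfig(n_subjects=50, seed=11)
    c1, p1 = simulate_cohort(cfg)
    c2, p2 = simulate_cohort(SimulationConfig(n_subjects=50, seed=11))
    pd.testing.assert_frame_equal(c1.subjects, c2.subjects)
    pd.testing.assert_frame_equal(c1.genotypes, c2.genotypes)
    pd.testing.assert_frame_equal(p1, p2)


def test_minimal_two_subject_cohort():
    cohort, phen = simulate_cohort(SimulationConfig(n_subjects=2, seed=0))
    assert len(cohort.subjects) == 2
    assert phen["subject_id"].isin(cohort.subjects["id"]).all()


def test_truth_record_roundtrips_json():
    cfg = SimulationConfig(n_subjects=10, seed=2,
                           snp_effects={"rs6265": (0.5, 2.0)},
                           age_interactions={"rs7138803": -0.07})
    cohort, _ = simulate_cohort(cfg)
    restored = json.loads(json.dumps(cohort.truth))
    assert restored == cohort.truth
    assert restored["snp_effects"]["rs6265"] == [0.5, 2.0]


def test_bw_snp_effect_hook_shifts_birth_weight():
    base = SimulationConfig(n_subjects=2000, seed=8)
    hooked = SimulationConfig(n_subjects=2000, seed=8,
                              bw_snp_effects={"rs6499640": 0.3})
    c0, _ = simulate_cohort(base)
    c1, _ = simulate_cohort(hooked)
    dose = c1.genotypes["rs6499640"].to_numpy(float)
    shift = c1.subjects["birth_weight"].to_numpy() - c0.subjects["birth_weight"].to_numpy()
    assert np.allclose(shift, 0.3 * dose)


@pytest.mark.parametrize("bad", [
    {"residual_sd": -1.0},
    {"random_corr": 1.5},
    {"visits_child_mean": 0.5},
    {"sex_ratio": 2.0},
    {"adult_age_range": (17.0, 45.0)},
])
def test_config_validation(bad):
    with pytest.raises(ValueError):
        SimulationConfig(n_subjects=10, **bad)


def test_config_yaml_roundtrip(tmp_path):
    import yaml
    cfg = SimulationConfig(n_subjects=25, seed=13, snp_effects={"rs29941": 0.4})
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    restored = SimulationConfig.from_file(path)
    assert restored.n_subjects == 25
    assert restored.snp_effects == {"rs29941": 0.4}
    assert restored.snp_panel.snp_ids == cfg.snp_panel.snp_ids
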