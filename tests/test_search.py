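"""Forward burden-score search: selection, ties, permutation null."""

import numpy as np
import pytest

from bmilong.panel import default_panel
from bmilong.search import (ForwardBurdenSearch, burden_effect,
                            forward_search, permutation_pvalue)
from bmilong.simulate import Cohort, SimulationConfig, simulate_cohort

PANEL5 = default_panel().subset(
    ["rs2568958", "rs13107325", "rs7138803", "rs8050136", "rs29941"])


def test_dominant_signal_selects_exactly_the_causal_snp():
    cfg = SimulationConfig(n_subjects=200, seed=50,
                           snp_effects={"rs7138803": 1.0},
                           random_intercept_sd=0.3, random_slope_sd=0.02,
                           residual_sd=0.3)
    cohort, phen = simulate_cohort(cfg)
    est = forward_search(cohort, phen, "child", panel=PANEL5)
    assert list(est.steps_["snp_id"]) == ["rs7138803"]
    # risk allele (the minor allele carries the positive effect) is reported
    assert est.steps_.iloc[0]["ref_allele"] == "A"
    beta, se = burden_effect(est)
    assert beta == pytest.approx(1.0, abs=3 * se)


def test_accepted_path_aic_strictly_decreases(effect_cohort):
    cohort, phen = effect_cohort
    est = forward_search(cohort, phen, "child")
    path = np.r_[est.baseline_aic_, est.steps_["modified_aic"].to_numpy()]
    assert (np.diff(path) < 0).all()
    assert est.min_aic_ <= est.baseline_aic_


def test_null_search_often_stops_quickly():
    accepted = []
    for seed in range(10):
        cfg = SimulationConfig(n_subjects=60, seed=600 + seed,
                               visits_child_mean=2.0, visits_adult_mean=1.0)
        cohort, phen = simulate_cohort(cfg)
        est = forward_search(cohort, phen, "child", panel=PANEL5,
                             compute_r2=False)
        path = np.r_[est.baseline_aic_, est.steps_["modified_aic"].to_numpy()]
        assert (np.diff(path) < 0).all()
        accepted.append(len(est.steps_))
    assert np.mean(accepted) < len(PANEL5)


def test_allele_flip_mirror_gives_identical_min_aic(effect_cohort):
    """Flipping every dosage (2-d, swapping allele labels) leaves the
    minimized AIC unchanged: the intercept absorbs the burden shift."""
    cohort, phen = effect_cohort
    est = forward_search(cohort, phen, "child", panel=PANEL5,
                         compute_r2=False)
    mirrored = Cohort(subjects=cohort.subjects,
                      genotypes=2.0 - cohort.genotypes, truth=cohort.truth)
    est_m = forward_search(mirrored, phen, "child", panel=PANEL5,
                           compute_r2=False)
    assert est_m.min_aic_ == pytest.approx(est.min_aic_, abs=1e-6)
    assert list(est_m.steps_["snp_id"]) == list(est.steps_["snp_id"])


def test_min_aic_invariant_to_panel_column_order(effect_cohort):
    cohort, phen = effect_cohort
    est = forward_search(cohort, phen, "child", panel=PANEL5,
                         compute_r2=False)
    reordered = PANEL5.subset(PANEL5.snp_ids[::-1])
    est_r = forward_search(cohort, phen, "child", panel=reordered,
                           compute_r2=False)
    assert est_r.min_aic_ == pytest.approx(est.min_aic_, abs=1e-6)


def test_monomorphic_snp_never_selected(null_cohort):
    cohort, phen = null_cohort
    geno = cohort.genotypes[PANEL5.snp_ids].copy()
    geno["rs29941"] = 2.0
    degenerate = Cohort(subjects=cohort.subjects, genotypes=geno,
                        truth=cohort.truth)
    est = forward_search(degenerate, phen, "child", compute_r2=False)
    assert "rs29941" not in set(est.steps_["snp_id"])


def test_all_monomorphic_raises(null_cohort):
    cohort, phen = null_cohort
    geno = cohort.genotypes[PANEL5.snp_ids] * 0.0
    with pytest.raises(ValueError, match="polymorphic"):
        forward_search(Cohort(subjects=cohort.subjects, genotypes=geno,
                              truth=cohort.truth), phen, "child")


def test_trace_r2_columns_monotone_cumulative(effect_cohort):
    cohort, phen = effect_cohort
    est = forward_search(cohort, phen, "child", panel=PANEL5)
    steps = est.steps_
    assert (steps["cum_r2_pct"] >= 0).all()
    assert (steps["single_r2_pct"] >= 0).all()
    assert steps[["step", "snp_id", "ref_allele"]].notna().all().all()


def test_zero_step_trace_is_valid():
    cfg = SimulationConfig(n_subjects=40, seed=604, visits_child_mean=1.5,
                           visits_adult_mean=1.0, residual_sd=4.0)
    cohort, phen = simulate_cohort(cfg)
    for seed in range(606, 640):
        cfg = SimulationConfig(n_subjects=40, seed=seed, visits_child_mean=1.5,
                               visits_adult_mean=1.0, residual_sd=4.0)
        cohort, phen = simulate_cohort(cfg)
        est = forward_search(cohort, phen, "child",
                             panel=PANEL5.subset(["rs13107325"]),
                             compute_r2=False)
        if len(est.steps_) == 0:
            assert est.min_aic_ == est.baseline_aic_
            assert est.burden_beta_ is None
            with pytest.raises(ValueError):
                burden_effect(est)
            with pytest.raises(ValueError):
                est.interaction_test("age")
            return
    pytest.fail("no zero-step search found in the scanned seeds")


def test_permutation_granularity_single_perm(null_cohort):
    cohort, phen = null_cohort
    p = permutation_pvalue(cohort, phen, "child", panel=PANEL5, n_perm=1,
                           seed=0)
    assert p in (0.0, 1.0)


def test_permutation_deterministic_given_seed(null_cohort):
    cohort, phen = null_cohort
    p1 = permutation_pvalue(cohort, phen, "child", panel=PANEL5, n_perm=30,
                            seed=5)
    p2 = permutation_pvalue(cohort, phen, "child", panel=PANEL5, n_perm=30,
                            seed=5)
    assert p1 == p2


def test_bmi_permutation_scheme_runs(null_cohort):
    cohort, phen = null_cohort
    est = ForwardBurdenSearch(n_perm=10, scheme="bmi", random_state=3,
                              compute_r2=False).fit(cohort, phen, "child",
                                                    panel=PANEL5)
    assert est.empirical_p_ is not None
    assert 0.0 <= est.empirical_p_ <= 1.0


def test_overfitting_decreases_with_noise():
    """Mean number of accepted SNPs under pure noise shrinks as residual
    variance grows (the per-SNP penalty bites harder)."""
    means = []
    for resid in (1.0, 3.0, 9.0):
        counts = []
        for seed in range(8):
            cfg = SimulationConfig(n_subjects=80, seed=700 + seed,
                                   visits_child_mean=2.0, visits_adult_mean=1.0,
                                   random_intercept_sd=0.0,
                                   random_slope_sd=0.0, residual_sd=resid)
            cohort, phen = simulate_cohort(cfg)
            est = forward_search(cohort, phen, "child", compute_r2=False)
            counts.append(len(est.steps_))
        means.append(np.mean(counts))
    assert means[0] >= means[-1]


def test_burden_interaction_test_recovers_age_modifier():
    causal = PANEL5.snp_ids
    cfg = SimulationConfig(n_subjects=658, seed=52,
                           snp_effects={c: 0.5 for c in causal},
                           age_interactions={c: -0.02 for c in causal})
    cohort, phen = simulate_cohort(cfg)
    est = forward_search(cohort, phen, "child")
    rec = est.interaction_test("age")
    assert rec["beta"] == pytest.approx(-0.02, abs=3 * rec["se"])
    assert 0 <= rec["p"] <= 1
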