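"""Mixed-model engine: oracles, invariants, Wald tests, modified AIC, R^2."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from bmilong.association import stratum_table
from bmilong.lmm import (MixedLMM, RankDeficientDesignError, fit_lmm,
                         marginal_r2, modified_aic, modified_aic_fit,
                         wald_test)
from bmilong.simulate import SimulationConfig, simulate_cohort


def _toy_long(n_subjects=5, visits=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for _ in range(visits):
            age = rng.uniform(4, 16)
            rows.append((f"S{i}", age, 17.0 + 0.5 * age + noise * rng.normal()))
    return pd.DataFrame(rows, columns=["subject_id", "age", "bmi"])


def test_noiseless_linear_recovery_ols_path():
    df = _toy_long()
    est = MixedLMM(random_structure="none").fit(
        df[["age"]].to_numpy(), df["bmi"].to_numpy(), feature_names=["age"])
    assert est.coef_ == pytest.approx([17.0, 0.5], abs=1e-10)


def test_near_noiseless_recovery_mixed_path():
    df = _toy_long(noise=1e-6)
    est = MixedLMM().fit(df[["age"]].to_numpy(), df["bmi"].to_numpy(),
                         groups=df["subject_id"], slope=df["age"],
                         feature_names=["age"])
    assert est.coef_ == pytest.approx([17.0, 0.5], abs=1e-4)


def test_no_random_effects_equals_ols_loglik():
    df = _toy_long(noise=1.0, n_subjects=20)
    X = df[["age"]].to_numpy()
    est = MixedLMM(random_structure="none").fit(X, df["bmi"].to_numpy())
    ols = sm.OLS(df["bmi"].to_numpy(), sm.add_constant(X)).fit()
    assert est.loglik_ == pytest.approx(ols.llf, abs=1e-8)


def test_loglik_matches_brute_force_mvn_density():
    """Tiny instance: profiled lnL equals the marginal normal density with
    V = Z G Z' + sigma2 I assembled blockwise at the fitted parameters."""
    rng = np.random.default_rng(3)
    rows = []
    for i in range(3):
        for _ in range(2):
            age = rng.uniform(5, 15)
            rows.append((f"S{i}", age,
                         18 + 0.4 * age + rng.normal(scale=1.0) + 0.5 * i))
    df = pd.DataFrame(rows, columns=["subject_id", "age", "bmi"])
    est = MixedLMM().fit(df[["age"]].to_numpy(), df["bmi"].to_numpy(),
                         groups=df["subject_id"], slope=df["age"],
                         feature_names=["age"])
    X = np.column_stack([np.ones(len(df)), df["age"]])
    mean = X @ est.coef_
    V = np.zeros((len(df), len(df)))
    for sid in df["subject_id"].unique():
        idx = np.flatnonzero((df["subject_id"] == sid).to_numpy())
        Z = np.column_stack([np.ones(idx.size), df["age"].to_numpy()[idx]])
        V[np.ix_(idx, idx)] = Z @ est.re_cov_ @ Z.T
    V += est.sigma2_ * np.eye(len(df))
    oracle = stats.multivariate_normal.logpdf(df["bmi"].to_numpy(), mean, V)
    assert est.loglik_ == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize("seed", [2, 4, 5])
def test_loglik_matches_statsmodels_mixedlm(seed):
    cfg = SimulationConfig(n_subjects=120, seed=seed, residual_sd=2.0,
                           random_intercept_sd=1.5, random_slope_sd=0.2,
                           random_corr=0.3)
    cohort, phen = simulate_cohort(cfg)
    child = stratum_table(cohort, phen, "child")
    ours = fit_lmm(child, [])
    X = np.column_stack([np.ones(len(child)),
                         child[["age", "sex", "birth_weight"]].to_numpy(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(child["bmi"].to_numpy(), X,
                         groups=child["subject_id"].to_numpy(),
                         exog_re=np.column_stack([np.ones(len(child)),
                                                  child["age"].to_numpy()])
                         ).fit(reml=False)
    # never worse than the reference optimizer, and equal when it converges
    assert ours.loglik_ >= res.llf - 1e-4
    if res.converged:
        assert ours.loglik_ == pytest.approx(res.llf, abs=1e-4)
        assert ours.coef_ == pytest.approx(np.asarray(res.fe_params), abs=1e-3)


def test_nested_loglik_consistency(null_cohort, child_table):
    cohort, _ = null_cohort
    small = fit_lmm(child_table, [])
    data = child_table.assign(
        dos=cohort.genotypes["rs29941"].loc[child_table["subject_id"]].to_numpy())
    large = fit_lmm(data, ["dos"])
    assert large.loglik_ >= small.loglik_ - 1e-6


def test_rank_deficient_design_names_columns(child_table):
    data = child_table.assign(age_copy=child_table["age"])
    with pytest.raises(RankDeficientDesignError, match="age"):
        fit_lmm(data, ["age_copy"])


def _fabricated_fit(beta, cov, names=None):
    est = MixedLMM()
    beta = np.asarray(beta, dtype=float)
    names = names or [f"b{i}" for i in range(beta.size)]
    est._finalize(names, beta, np.asarray(cov, dtype=float), 1.0,
                  np.eye(2), -100.0, n_obs=50, n_groups=10, n_varcomp=4,
                  converged=True, theta=np.zeros(3))
    return est


def test_wald_zero_estimate_gives_p_one():
    fit = _fabricated_fit([0.0], [[0.25]])
    assert wald_test(fit, ["b0"]) == pytest.approx(1.0)


def test_wald_single_term_normal_quantile():
    fit = _fabricated_fit([1.96], [[1.0]])
    assert wald_test(fit, ["b0"]) == pytest.approx(0.05, abs=1e-3)


def test_wald_two_terms_block_diagonal_adds():
    z1, z2 = 1.3, 2.1
    fit = _fabricated_fit([z1, z2], np.eye(2))
    expected = stats.chi2.sf(z1 ** 2 + z2 ** 2, 2)
    assert wald_test(fit, ["b0", "b1"]) == pytest.approx(expected)


def test_wald_singular_covariance_raises():
    fit = _fabricated_fit([1.0, 1.0], [[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(np.linalg.LinAlgError):
        wald_test(fit, ["b0", "b1"])


def test_modified_aic_hand_arithmetic():
    assert modified_aic(-100.0, n_snps=3, n_non_snp=6) == pytest.approx(218.0)


def test_modified_aic_penalty_increment():
    base = modified_aic(-500.0, 4, 8)
    assert modified_aic(-500.0, 5, 8) == pytest.approx(base + 2.0)


def test_modified_aic_reduces_to_standard_form_at_zero_snps():
    lnl = -123.4
    assert modified_aic(lnl, 0, 8) == pytest.approx(2 * 8 - 2 * lnl)


def test_modified_aic_fit_counts_non_snp_params(child_table):
    fit = fit_lmm(child_table, [])
    # 4 fixed covariates + 4 variance components
    assert modified_aic_fit(fit, 0, 0) == pytest.approx(
        2 * 8 - 2 * fit.loglik_)


def test_marginal_r2_limits(rng):
    y = rng.normal(size=100)
    assert marginal_r2(0.0, rng.normal(size=100), y) == 0.0
    s = rng.normal(size=100)
    assert marginal_r2(1.0, s, s) == pytest.approx(100.0)
    assert marginal_r2(3.0, np.ones(100), y) == 0.0  # constant predictor


def test_marginal_r2_variance_decomposition(rng):
    """Additive SNP: R^2 -> 100 * b^2 2pq / sigma_T^2 at large n."""
    n, p, b, sd = 10_000, 0.3, 0.5, 2.0
    d = rng.binomial(2, p, size=n).astype(float)
    y = b * d + rng.normal(scale=sd, size=n)
    expected = 100 * b ** 2 * 2 * p * (1 - p) / (b ** 2 * 2 * p * (1 - p) + sd ** 2)
    assert marginal_r2(b, d, y) == pytest.approx(expected, rel=0.05)


def test_summary_dict_serializes(child_table):
    import json
    fit = fit_lmm(child_table, [])
    blob = json.dumps(fit.summary_dict())
    assert "loglik" in blob and "re_cov" in blob
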