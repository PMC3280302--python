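"""Longitudinal linear mixed model fit by maximum likelihood.

This is the engine behind every scan and the forward burden search: BMI is
regressed on fixed covariates (intercept, age in years, sex, birth weight in kg,
plus whatever genetic term the caller supplies) with a per-subject random
intercept and random age slope carrying an unstructured 2x2 covariance.
Estimation is maximum likelihood, not REML, because downstream model comparison
(likelihood ratios, the modified AIC of the joint search) compares models that
differ in their fixed effects.

The likelihood is profiled: for a fixed residual-scaled random-effect covariance
Psi, the GLS fixed effects and the ML residual variance are closed-form, leaving
a q(q+1)/2-dimensional optimization (q = 2 by default) done by Nelder-Mead on a
log-Cholesky parameterization of Psi.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from ._kernels import deviance_q1, deviance_q2, nelder_mead_q2

__all__ = [
    "MixedLMM", "fit_lmm", "wald_test", "modified_aic", "marginal_r2",
    "RankDeficientDesignError", "ConvergenceError",
]

BASE_COVARIATES = ["age", "sex", "birth_weight"]

_BIG = 1.0e300
_THETA_CLIP = 12.0


class RankDeficientDesignError(ValueError):
    """Design matrix is not full rank; names the collinear columns."""


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit."""


def _psi_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Log-Cholesky map: theta -> Psi (residual-scaled RE covariance)."""
    t = np.clip(theta, -_THETA_CLIP, _THETA_CLIP)
    if q == 1:
        return np.array([[np.exp(2.0 * t[0])]])
    l00 = np.exp(t[0])
    l11 = np.exp(t[1])
    l10 = t[2]
    return np.array([
        [l00 * l00, l00 * l10],
        [l00 * l10, l10 * l10 + l11 * l11],
    ])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientDesignError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


def _precompute(X: np.ndarray, y: np.ndarray, Z: np.ndarray, order: np.ndarray,
                bounds: np.ndarray):
    """Per-subject cross-products (A, B, c) plus design totals.

    ``order`` sorts observations by subject; ``bounds`` are the reduceat segment
    starts of the sorted subject blocks.
    """
    n, p = X.shape
    q = Z.shape[1]
    Xs, ys, Zs = X[order], y[order], Z[order]
    prods = np.empty((n, q * q + q * p + q))
    k = 0
    for a in range(q):
        for b in range(q):
            prods[:, k] = Zs[:, a] * Zs[:, b]
            k += 1
    for a in range(q):
        for b in range(p):
            prods[:, k] = Zs[:, a] * Xs[:, b]
            k += 1
    for a in range(q):
        prods[:, k] = Zs[:, a] * ys
        k += 1
    sums = np.add.reduceat(prods, bounds, axis=0)
    s = sums.shape[0]
    A = sums[:, : q * q].reshape(s, q, q)
    B = sums[:, q * q: q * q + q * p].reshape(s, q, p)
    c = sums[:, q * q + q * p:].reshape(s, q)
    sxx = X.T @ X
    sxy = X.T @ y
    syy = float(y @ y)
    return A, B, c, sxx, sxy, syy


def _ols_fit(X: np.ndarray, y: np.ndarray):
    """Closed-form ML (OLS) fit used for random_structure='none'."""
    n = X.shape[0]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 > 0:
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    else:
        loglik = np.inf  # degenerate noiseless fit: density unbounded
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, sigma2, loglik, cov


class MixedLMM(BaseEstimator):
    """ML linear mixed model with per-subject random intercept and/or age slope.

    Parameters
    ----------
    random_structure : {"intercept_slope", "intercept", "slope", "none"}
        Random-effect design per subject. The default models correlated random
        intercept and random age slope (unstructured 2x2 covariance); growth
        data with between-subject level differences needs both. "none" reduces
        to ordinary least squares.
    fit_intercept : bool
        Prepend a fixed intercept column.
    maxiter, fatol, xatol : Nelder-Mead controls for the profiled deviance.

    Fitted attributes (trailing underscore) include ``coef_``, ``se_``,
    ``cov_params_``, ``sigma2_`` (residual variance), ``re_cov_`` (random-effect
    covariance on the data scale), ``loglik_``, ``n_obs_``, ``n_groups_``,
    ``n_fixed_``, ``n_varcomp_`` and ``converged_``.
    """

    def __init__(self, random_structure: str = "intercept_slope",
                 fit_intercept: bool = True, maxiter: int = 1000,
                 fatol: float = 1e-9, xatol: float = 1e-6):
        self.random_structure = random_structure
        self.fit_intercept = fit_intercept
        self.maxiter = maxiter
        self.fatol = fatol
        self.xatol = xatol

    # -- internals -----------------------------------------------------------

    def _q(self) -> int:
        return {"intercept_slope": 2, "intercept": 1, "slope": 1, "none": 0}[
            self.random_structure
        ]

    def fit(self, X, y, groups=None, slope=None, feature_names=None,
            start_theta=None):
        """Fit by maximum likelihood.

        Parameters
        ----------
        X : (n_obs, p) fixed-effect design (without intercept unless
            ``fit_intercept=False``).
        y : (n_obs,) response (BMI).
        groups : (n_obs,) subject identifiers; required unless
            ``random_structure='none'``.
        slope : (n_obs,) covariate carrying the random slope (age); required
            for structures containing a slope.
        start_theta : optional warm start for the variance parameters.
        """
        if self.random_structure not in ("intercept_slope", "intercept",
                                         "slope", "none"):
            raise ValueError(f"unknown random_structure {self.random_structure!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if X.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        feature_names = list(feature_names)
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
            feature_names = ["intercept"] + feature_names
        _check_rank(X, feature_names)
        q = self._q()

        if q == 0:
            beta, sigma2, loglik, cov = _ols_fit(X, y)
            self._finalize(feature_names, beta, cov, sigma2,
                           np.zeros((0, 0)), loglik, n, n_groups=n,
                           n_varcomp=1, converged=True, theta=np.empty(0))
            return self

        if groups is None:
            raise ValueError("groups required for random-effect structures")
        codes, uniques = pd.factorize(np.asarray(groups).ravel())
        if uniques.size < 2:
            raise ValueError("need at least 2 subjects")
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        bounds = np.flatnonzero(np.r_[True, np.diff(sorted_codes) > 0])

        if self.random_structure == "intercept":
            Z = np.ones((n, 1))
        else:
            if slope is None:
                raise ValueError("slope covariate (age) required for random slope")
            zs = np.asarray(slope, dtype=float).ravel()
            if self.random_structure == "slope":
                Z = zs[:, None]
            else:
                Z = np.column_stack([np.ones(n), zs])

        pre = _precompute(X, y, Z, order, bounds)
        theta, dev, beta, sigma2, sxx_adj, converged = _optimize_profiled(
            pre, n, q, start_theta=start_theta, maxiter=self.maxiter,
            fatol=self.fatol, xatol=self.xatol,
        )
        psi = _psi_from_theta(theta, q)
        cov = sigma2 * np.linalg.inv(sxx_adj)
        self._finalize(feature_names, beta, cov, sigma2, sigma2 * psi,
                       -0.5 * dev, n, n_groups=int(uniques.size),
                       n_varcomp=q * (q + 1) // 2 + 1, converged=converged,
                       theta=theta)
        return self

    def _finalize(self, names, beta, cov, sigma2, re_cov, loglik, n_obs,
                  n_groups, n_varcomp, converged, theta):
        self.feature_names_ = names
        self.coef_ = np.asarray(beta, dtype=float)
        self.cov_params_ = np.asarray(cov, dtype=float)
        self.se_ = np.sqrt(np.diag(self.cov_params_))
        self.sigma2_ = float(sigma2)
        self.re_cov_ = np.asarray(re_cov, dtype=float)
        self.loglik_ = float(loglik)
        self.n_obs_ = int(n_obs)
        self.n_groups_ = int(n_groups)
        self.n_fixed_ = len(names)
        self.n_varcomp_ = int(n_varcomp)
        self.converged_ = bool(converged)
        self.theta_ = np.asarray(theta, dtype=float)

    # -- API -----------------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Population-level (fixed-effects) prediction."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X @ self.coef_

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef_, "se": self.se_}, index=self.feature_names_
        )

    def summary_dict(self) -> dict:
        """JSON-serializable fit record."""
        return {
            "coef": dict(zip(self.feature_names_, map(float, self.coef_))),
            "se": dict(zip(self.feature_names_, map(float, self.se_))),
            "sigma2": self.sigma2_,
            "re_cov": self.re_cov_.tolist(),
            "loglik": self.loglik_,
            "n_obs": self.n_obs_,
            "n_groups": self.n_groups_,
            "n_fixed": self.n_fixed_,
            "n_varcomp": self.n_varcomp_,
            "converged": self.converged_,
        }


def _optimize_profiled(pre, n_obs, q, start_theta=None, maxiter=1000,
                       fatol=1e-9, xatol=1e-6):
    A, B, c, sxx, sxy, syy = pre

    if q == 1:
        def objective(t):
            psi = _psi_from_theta(t, 1)
            return deviance_q1(psi[0, 0], A, B, c, sxx, sxy, syy, n_obs)[0]
        x0 = (np.array([-1.0]) if start_theta is None
              else np.asarray(start_theta, float))
        step = 1.0 if start_theta is None else 0.25
        simplex = np.vstack([x0] + [x0 + step * e for e in np.eye(x0.size)])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": fatol, "xatol": xatol,
                     "initial_simplex": simplex},
        )
        theta, success = res.x, bool(res.success)
    else:
        x0 = (np.array([0.0, -3.0, 0.0]) if start_theta is None
              else np.asarray(start_theta, float))
        step = 0.75 if start_theta is None else 0.2
        theta, _, success = nelder_mead_q2(
            np.ascontiguousarray(x0, dtype=float), step,
            A, B, c, sxx, sxy, syy, n_obs, maxiter, fatol, xatol,
        )
    psi = _psi_from_theta(theta, q)
    if q == 1:
        dev, beta, sigma2, sxx_adj = deviance_q1(psi[0, 0], A, B, c, sxx, sxy,
                                                 syy, n_obs)
    else:
        dev, beta, sigma2, sxx_adj = deviance_q2(psi, A, B, c, sxx, sxy, syy,
                                                 n_obs)
    converged = success and dev < _BIG
    return theta, dev, beta, sigma2, sxx_adj, converged


def fit_lmm(data: pd.DataFrame, genetic_cols: list[str] | None = None,
            response: str = "bmi", covariates: list[str] | None = None,
            random_structure: str = "intercept_slope", **kwargs) -> MixedLMM:
    """Fit the longitudinal model on a long-format observation table.

    ``data`` must carry one row per (subject, visit) with columns
    ``subject_id``, ``age``, the response, the fixed covariates and any genetic
    term columns. Genetic columns are appended after the base covariates.
    """
    if covariates is None:
        covariates = BASE_COVARIATES
    genetic_cols = list(genetic_cols or [])
    cols = list(covariates) + genetic_cols
    X = data[cols].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    est = MixedLMM(random_structure=random_structure, **kwargs)
    est.fit(X, y, groups=data["subject_id"].to_numpy(),
            slope=data["age"].to_numpy(dtype=float), feature_names=cols)
    return est


def wald_test(fit: MixedLMM, terms) -> float:
    """Joint Wald chi-square p-value for the named coefficients.

    ``terms`` is a list of feature names (or integer positions); the statistic
    is beta' Cov^{-1} beta with df = len(terms).
    """
    idx = []
    for t in terms:
        if isinstance(t, str):
            if t not in fit.feature_names_:
                raise KeyError(f"term {t!r} not in fitted model")
            idx.append(fit.feature_names_.index(t))
        else:
            idx.append(int(t))
    idx = np.asarray(idx)
    beta = fit.coef_[idx]
    cov = fit.cov_params_[np.ix_(idx, idx)]
    try:
        stat = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular coefficient covariance for terms {terms}"
        ) from exc
    if stat < 0:
        stat = 0.0
    return float(stats.chi2.sf(stat, df=len(idx)))


def modified_aic(loglik: float, n_snps: int, n_non_snp: int) -> float:
    """2 * (n_snps + n_non_snp) - 2 * lnL.

    The per-SNP penalty replaces the usual per-coefficient penalty: a burden
    score built from k SNPs costs k penalty units even though it is fitted with
    a single coefficient (that coefficient is absorbed into the SNP count and
    never double-counted). ``n_non_snp`` counts every other estimated parameter
    — the fixed covariate coefficients plus the variance components — and is
    constant across compared models, so it shifts but never reorders them.
    """
    return 2.0 * (n_snps + n_non_snp) - 2.0 * loglik


def modified_aic_fit(fit: MixedLMM, n_snps: int, n_genetic_terms: int) -> float:
    """Modified AIC for a fitted model with ``n_genetic_terms`` genetic columns."""
    if not fit.converged_:
        raise ConvergenceError("modified AIC requires a converged fit")
    n_non_snp = (fit.n_fixed_ - n_genetic_terms) + fit.n_varcomp_
    return modified_aic(fit.loglik_, n_snps, n_non_snp)


def marginal_r2(beta_genetic: float, predictor, y) -> float:
    """Percent of total phenotypic variance carried by a genetic fixed effect.

    100 * Var(beta * S) / Var(y) over observations, where S is the genetic
    predictor (a dosage or burden score). A constant predictor returns 0.
    """
    s = np.asarray(predictor, dtype=float)
    y = np.asarray(y, dtype=float)
    vy = y.var()
    if vy == 0:
        return 0.0
    return float(100.0 * (beta_genetic * s).var() / vy)
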