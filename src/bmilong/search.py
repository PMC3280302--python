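"""Heuristic forward search for the best joint-effect burden model.

SNPs are added one at a time. A candidate is a (SNP, reference allele) pair;
its trial burden score per subject is the current burden plus that subject's
count of the reference allele. The trial burden enters the longitudinal mixed
model as the single genetic covariate (with age, sex, birth weight and the
random intercept + age slope), and the candidate's score is the modified AIC

    2 * (k + n_non_snp) - 2 * lnL,

where k is the number of selected SNPs (the burden coefficient is penalized
per SNP it aggregates, not as one extra coefficient) and n_non_snp counts the
four covariate coefficients plus the four variance components. The search
accepts the minimum-AIC candidate whenever it is strictly below the current
AIC and stops otherwise. Significance of the selected model comes from a
permutation null: the genotype rows are permuted across subjects (severing the
genotype-phenotype link while preserving trajectories, covariates and LD), the
whole search is rerun per permutation, and the empirical p is the fraction of
permuted minimized AICs at or below the observed one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .association import stratum_table
from .lmm import _optimize_profiled, fit_lmm, marginal_r2, wald_test
from .panel import SnpPanel, default_panel
from .simulate import Cohort

log = logging.getLogger(__name__)

# Allele-flipped candidates sit on affinely identical likelihood surfaces, but
# their cross-products are computed from different float operations; the
# optimizer can diverge by ~1e-6 deviance units between the two. Genuine
# between-SNP AIC gaps are orders of magnitude larger.
_AIC_TIE_TOL = 1e-5
_AIC_IMPROVE_TOL = 1e-9


class _Workspace:
    """Precomputed design pieces for repeated burden-model fits on one stratum.

    The base fixed design (intercept, age, sex, birth weight) and the
    random-effect cross-products never change between candidate fits; only the
    burden column does, so each fit needs a handful of segment sums.
    """

    def __init__(self, data: pd.DataFrame, random_structure: str = "intercept_slope"):
        self.data = data
        self.y = data["bmi"].to_numpy(dtype=float)
        age = data["age"].to_numpy(dtype=float)
        n = len(data)
        self.n_obs = n
        self.codes, self.subject_ids = pd.factorize(data["subject_id"].to_numpy())
        self.n_subjects = len(self.subject_ids)
        self.order = np.argsort(self.codes, kind="stable")
        sorted_codes = self.codes[self.order]
        self.bounds = np.flatnonzero(np.r_[True, np.diff(sorted_codes) > 0])
        if random_structure != "intercept_slope":
            raise NotImplementedError("search supports the intercept+slope structure")
        self.q = 2
        self.Z = np.column_stack([np.ones(n), age])
        self.Zs = self.Z[self.order]
        self.Xbase = np.column_stack([
            np.ones(n), age,
            data["sex"].to_numpy(dtype=float),
            data["birth_weight"].to_numpy(dtype=float),
        ])
        Xs, ys = self.Xbase[self.order], self.y[self.order]
        q, p = self.q, self.Xbase.shape[1]
        prods = np.empty((n, q * q + q * p + q))
        k = 0
        for a in range(q):
            for b in range(q):
                prods[:, k] = self.Zs[:, a] * self.Zs[:, b]; k += 1
        for a in range(q):
            for b in range(p):
                prods[:, k] = self.Zs[:, a] * Xs[:, b]; k += 1
        for a in range(q):
            prods[:, k] = self.Zs[:, a] * ys; k += 1
        sums = np.add.reduceat(prods, self.bounds, axis=0)
        s = sums.shape[0]
        self.A = np.ascontiguousarray(sums[:, :q * q].reshape(s, q, q))
        self.Bbase = sums[:, q * q:q * q + q * p].reshape(s, q, p)
        self.czy = sums[:, q * q + q * p:].reshape(s, q)
        self.sxx_base = self.Xbase.T @ self.Xbase
        self.sxy_base = self.Xbase.T @ self.y
        self.syy = float(self.y @ self.y)
        self.n_non_snp = self.Xbase.shape[1] + (q * (q + 1) // 2 + 1)

    def obs_values(self, per_subject: np.ndarray) -> np.ndarray:
        """Broadcast a per-subject vector onto observations."""
        return per_subject[self.codes]

    def fit_base(self, start_theta=None):
        pre = (self.A, self.Bbase, self.czy, self.sxx_base, self.sxy_base,
               self.syy, )
        return self._run(pre[0], pre[1], pre[2], pre[3], pre[4], start_theta)

    def fit_with_burden(self, burden_subj: np.ndarray, start_theta=None):
        """Fit base covariates + one burden column (per-subject values)."""
        g = self.obs_values(burden_subj)
        if np.ptp(g) == 0.0:
            return None  # constant burden: collinear with the intercept
        gs = g[self.order]
        zg = np.add.reduceat(self.Zs * gs[:, None], self.bounds, axis=0)
        B = np.concatenate([self.Bbase, zg[:, :, None]], axis=2)
        p = self.Xbase.shape[1] + 1
        sxx = np.empty((p, p))
        sxx[:p - 1, :p - 1] = self.sxx_base
        xg = self.Xbase.T @ g
        sxx[:p - 1, p - 1] = xg
        sxx[p - 1, :p - 1] = xg
        sxx[p - 1, p - 1] = float(g @ g)
        sxy = np.append(self.sxy_base, float(g @ self.y))
        return self._run(self.A, np.ascontiguousarray(B), self.czy, sxx, sxy,
                         start_theta)

    def _run(self, A, B, czy, sxx, sxy, start_theta):
        # Candidate ranking needs the deviance to ~1e-3 (AIC penalty unit is 2),
        # so the search runs the optimizer at a looser tolerance than the
        # public engine default.
        try:
            theta, dev, beta, sigma2, sxx_adj, converged = _optimize_profiled(
                (A, B, czy, sxx, sxy, self.syy), self.n_obs, self.q,
                start_theta=start_theta, fatol=1e-6, xatol=1e-4,
            )
        except np.linalg.LinAlgError:
            return None
        if not converged:
            return None
        cov = sigma2 * np.linalg.inv(sxx_adj)
        return {"theta": theta, "loglik": -0.5 * dev, "beta": beta,
                "cov": cov, "sigma2": sigma2}


def _impute_dosages(genotypes: pd.DataFrame) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages (burden construction only)."""
    g = genotypes.to_numpy(dtype=float)
    if np.isnan(g).any():
        means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = means[idx[1]]
    return g


class ForwardBurdenSearch(BaseEstimator):
    """Greedy forward selection of a reference-allele burden score.

    Parameters
    ----------
    n_perm : int
        Permutations for the empirical p-value (0 disables). The study-scale
        choice is 10,000; the default 1,000 keeps desk runs short.
    scheme : {"genotype", "bmi"}
        Permutation scheme. "genotype" permutes whole subject genotype rows
        across subjects, preserving trajectories, covariates and within-subject
        correlation — the targeted genotype-phenotype null. "bmi" reassigns
        whole BMI trajectories (with their ages) across subjects instead, the
        literal reading of phenotype permutation.
    max_steps : optional cap on accepted SNPs (None = panel size).
    compute_r2 : record per-step cumulative and single-variant variance traces.
    random_state : seed for the permutation generator.

    Fitted attributes: ``steps_`` (trace table: step, snp_id, ref_allele,
    modified_aic, cum_r2_pct, single_r2_pct), ``baseline_aic_``, ``min_aic_``,
    ``burden_``, ``burden_beta_``, ``burden_se_``, ``final_loglik_``,
    ``empirical_p_``, ``perm_aics_``.
    """

    def __init__(self, n_perm: int = 1000, scheme: str = "genotype",
                 max_steps: int | None = None, compute_r2: bool = True,
                 random_state: int | None = None):
        self.n_perm = n_perm
        self.scheme = scheme
        self.max_steps = max_steps
        self.compute_r2 = compute_r2
        self.random_state = random_state

    def fit(self, cohort: Cohort, phenotype: pd.DataFrame,
            stratum: str = "child", panel: SnpPanel | None = None):
        if self.scheme not in ("genotype", "bmi"):
            raise ValueError("scheme must be 'genotype' or 'bmi'")
        data = stratum_table(cohort, phenotype, stratum)
        ws = _Workspace(data)
        genotypes = cohort.genotypes.loc[ws.subject_ids]
        if panel is not None:
            genotypes = genotypes[panel.snp_ids]
        self._allele_labels = _allele_labels(genotypes.columns, panel)
        G = _impute_dosages(genotypes)
        if not (np.ptp(G, axis=0) > 0).any():
            raise ValueError("need at least one polymorphic SNP")
        self.snp_ids_ = list(genotypes.columns)
        self.stratum_ = stratum

        trace, burden, final, base = _run_search(
            ws, G, self.max_steps)
        self.baseline_aic_ = base["aic"]
        self.steps_raw_ = trace
        self.burden_ = burden
        self._ws = ws
        self._G = G
        if trace:
            self.min_aic_ = trace[-1]["aic"]
            self.final_loglik_ = final["loglik"]
            self.burden_beta_ = float(final["beta"][-1])
            self.burden_se_ = float(np.sqrt(final["cov"][-1, -1]))
            self._final_theta = final["theta"]
        else:
            self.min_aic_ = base["aic"]
            self.final_loglik_ = base["loglik"]
            self.burden_beta_ = None
            self.burden_se_ = None
            self._final_theta = base["theta"]
        self.steps_ = self._trace_table(ws, G, trace)
        if self.n_perm:
            self.perm_aics_ = self._permute(cohort, phenotype, stratum)
            self.empirical_p_ = float(
                np.mean(self.perm_aics_ <= self.min_aic_))
        else:
            self.perm_aics_ = None
            self.empirical_p_ = None
        return self

    # -- reporting -----------------------------------------------------------

    def _trace_table(self, ws, G, trace) -> pd.DataFrame:
        rows = []
        burden = np.zeros(ws.n_subjects)
        for step, rec in enumerate(trace, start=1):
            j, flip = rec["snp"], rec["flip"]
            dose = 2.0 - G[:, j] if flip else G[:, j]
            burden = burden + dose
            row = {"step": step, "snp_id": self.snp_ids_[j],
                   "ref_allele": self._allele_labels[j][1 if flip else 0],
                   "modified_aic": rec["aic"],
                   "cum_r2_pct": np.nan, "single_r2_pct": np.nan}
            if self.compute_r2:
                row["cum_r2_pct"] = marginal_r2(
                    rec["beta"][-1], ws.obs_values(burden), ws.y)
                single = ws.fit_with_burden(dose)
                if single is not None:
                    row["single_r2_pct"] = marginal_r2(
                        single["beta"][-1], ws.obs_values(dose), ws.y)
            rows.append(row)
        return pd.DataFrame(rows, columns=["step", "snp_id", "ref_allele",
                                           "modified_aic", "cum_r2_pct",
                                           "single_r2_pct"])

    # -- permutation null ----------------------------------------------------

    def _permute(self, cohort, phenotype, stratum) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        aics = np.empty(self.n_perm)
        if self.scheme == "genotype":
            ws = self._ws
            for b in range(self.n_perm):
                perm = rng.permutation(ws.n_subjects)
                trace, _, _, base = _run_search(ws, self._G[perm], self.max_steps)
                aics[b] = trace[-1]["aic"] if trace else base["aic"]
        else:  # literal subject-block BMI permutation
            for b in range(self.n_perm):
                perm = rng.permutation(len(cohort.subjects))
                relabel = dict(zip(cohort.subjects["id"].to_numpy(),
                                   cohort.subjects["id"].to_numpy()[perm]))
                phen_b = phenotype.assign(
                    subject_id=phenotype["subject_id"].map(relabel))
                data = stratum_table(cohort, phen_b, stratum)
                ws = _Workspace(data)
                G = self._G[
                    pd.Index(self._ws.subject_ids).get_indexer(ws.subject_ids)]
                trace, _, _, base = _run_search(ws, G, self.max_steps)
                aics[b] = trace[-1]["aic"] if trace else base["aic"]
        return aics

    # -- post-hoc tests ------------------------------------------------------

    def interaction_test(self, modifier: str) -> dict:
        """Burden x modifier product term added to the final model.

        Returns the product coefficient (per year or per kg), its SE, and the
        Wald p-value. Requires at least one accepted SNP.
        """
        if self.burden_beta_ is None:
            raise ValueError("no SNP accepted: burden model unavailable")
        if modifier not in ("age", "birth_weight"):
            raise ValueError("modifier must be 'age' or 'birth_weight'")
        ws = self._ws
        data = ws.data.assign(burden=ws.obs_values(self.burden_))
        data = data.assign(
            burden_x_mod=data["burden"] * data[modifier].to_numpy(dtype=float))
        fit = fit_lmm(data, ["burden", "burden_x_mod"])
        idx = fit.feature_names_.index("burden_x_mod")
        return {"modifier": modifier, "beta": float(fit.coef_[idx]),
                "se": float(fit.se_[idx]),
                "p": wald_test(fit, ["burden_x_mod"])}


def _allele_labels(snp_ids, panel: SnpPanel | None) -> list[tuple[str, str]]:
    """(minor, major) allele letters per SNP, from the panel when known."""
    if panel is None:
        try:
            panel = default_panel().subset(list(snp_ids))
        except KeyError:
            return [("minor", "major")] * len(snp_ids)
    return [panel.alleles(s) for s in snp_ids]


def _run_search(ws: _Workspace, G: np.ndarray, max_steps: int | None):
    """Greedy loop shared by the observed search and every permutation.

    Returns (trace, final_burden, final_fit, base_fit); each trace record
    holds the accepted candidate's column index, allele flip flag, fit and AIC.
    """
    m = G.shape[1]
    base = ws.fit_base()
    if base is None:
        raise RuntimeError("baseline covariates-only model failed to converge")
    base["aic"] = 2.0 * (0 + ws.n_non_snp) - 2.0 * base["loglik"]
    remaining = list(range(m))
    burden = np.zeros(ws.n_subjects)
    current_aic = base["aic"]
    theta = base["theta"]
    trace = []
    final = base
    limit = m if max_steps is None else min(max_steps, m)
    while len(trace) < limit and remaining:
        k = len(trace) + 1
        best = None
        for j in remaining:
            for flip in (False, True):
                dose = 2.0 - G[:, j] if flip else G[:, j]
                fit = ws.fit_with_burden(burden + dose, start_theta=theta)
                if fit is None:
                    continue
                aic = 2.0 * (k + ws.n_non_snp) - 2.0 * fit["loglik"]
                cand = (aic, j, flip, fit)
                if best is None or _better(cand, best):
                    best = cand
        if best is None:
            break
        aic, j, flip, fit = best
        if aic >= current_aic - _AIC_IMPROVE_TOL:
            break
        dose = 2.0 - G[:, j] if flip else G[:, j]
        burden = burden + dose
        trace.append({"snp": j, "flip": flip, "aic": aic,
                      "beta": fit["beta"]})
        current_aic = aic
        theta = fit["theta"]
        final = fit
        remaining.remove(j)
    return trace, burden, final, base


def _better(cand, best) -> bool:
    """Candidate ordering with the documented tie-break.

    Lower AIC wins; within ties (1e-5) a positive burden coefficient is
    preferred (risk-allele reporting convention), then the lower panel index.
    Candidates arrive in (panel index, minor-then-major) order, so keeping the
    incumbent on a full tie realizes the index preference.
    """
    aic_c, j_c, _, fit_c = cand
    aic_b, j_b, _, fit_b = best
    if aic_c < aic_b - _AIC_TIE_TOL:
        return True
    if aic_c > aic_b + _AIC_TIE_TOL:
        return False
    pos_c = fit_c["beta"][-1] > 0
    pos_b = fit_b["beta"][-1] > 0
    if pos_c != pos_b:
        return pos_c
    return False


# -- module-level wrappers ---------------------------------------------------

def forward_search(cohort: Cohort, phenotype: pd.DataFrame, stratum: str,
                   panel: SnpPanel | None = None,
                   **kwargs) -> ForwardBurdenSearch:
    """Run the forward search without permutations; returns the fitted searcher."""
    kwargs.setdefault("n_perm", 0)
    est = ForwardBurdenSearch(**kwargs)
    return est.fit(cohort, phenotype, stratum=stratum, panel=panel)


def burden_effect(est: ForwardBurdenSearch) -> tuple[float, float]:
    """Final per-allele burden effect (kg/m2 per reference-allele copy) and SE."""
    if est.burden_beta_ is None:
        raise ValueError("no SNP accepted: burden effect undefined")
    return est.burden_beta_, est.burden_se_


def permutation_pvalue(cohort: Cohort, phenotype: pd.DataFrame, stratum: str,
                       panel: SnpPanel | None = None, n_perm: int = 1000,
                       seed: int | None = None, scheme: str = "genotype",
                       max_steps: int | None = None) -> float:
    """Empirical p of the observed minimized AIC against the permutation null."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    est = ForwardBurdenSearch(n_perm=n_perm, scheme=scheme, compute_r2=False,
                              random_state=seed, max_steps=max_steps)
    est.fit(cohort, phenotype, stratum=stratum, panel=panel)
    return est.empirical_p_


def search_interaction_tests(est: ForwardBurdenSearch, modifier: str) -> dict:
    """Module-level wrapper over :meth:`ForwardBurdenSearch.interaction_test`."""
    return est.interaction_test(modifier)


def plot_variance_trace(est: ForwardBurdenSearch, path) -> None:
    """Cumulative (solid) and single-variant (dashed) explained-variance trace,
    with the reference allele labelled at the top of each column."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = est.steps_
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(steps)), 3.5))
    if len(steps):
        x = np.arange(1, len(steps) + 1)
        ax.plot(x, steps["cum_r2_pct"], "-o", color="k", label="cumulative")
        ax.plot(x, steps["single_r2_pct"], "--s", color="gray",
                label="single variant")
        top = float(np.nanmax(steps["cum_r2_pct"])) or 1.0
        for xi, allele in zip(x, steps["ref_allele"]):
            ax.text(xi, top * 1.05, allele, ha="center", fontsize=8)
        ax.set_xticks(x)
        ax.set_xticklabels(steps["snp_id"], rotation=90, fontsize=7)
    ax.set_ylabel("explained BMI variance (%)")
    ax.set_xlabel("sequentially added SNPs")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
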