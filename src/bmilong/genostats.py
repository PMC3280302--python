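"""Per-SNP genotype QC statistics: allele frequency, heterozygosity, HWE.

Dosages count copies of the minor allele (0/1/2); missing entries are NaN and
are excluded pairwise from every statistic, never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class EmptyGenotypeError(ValueError):
    """No non-missing dosages available for a statistic."""


class MonomorphicError(ValueError):
    """Statistic undefined for a SNP with a single observed allele."""


def _clean(dosages) -> np.ndarray:
    d = np.asarray(dosages, dtype=float).ravel()
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise EmptyGenotypeError("all dosages missing")
    bad = ~np.isin(d, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError(f"non-dosage values present: {np.unique(d[bad])}")
    return d


def minor_allele_frequency(dosages) -> float:
    """Sample frequency of the counted allele: sum(d) / (2 * n_called).

    If the counted allele turns out not to be the minor one in this sample
    (frequency > 0.5), the value is still returned on the stored coding and a
    warning is logged; QC never re-polarizes.
    """
    d = _clean(dosages)
    freq = float(d.sum() / (2.0 * d.size))
    if freq > 0.5:
        log.warning("counted-allele frequency %.3f exceeds 0.5 (minor/major flip)", freq)
    return freq


def expected_heterozygosity(p: float) -> float:
    """Hardy-Weinberg expected heterozygosity 2p(1-p) at allele frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    return 2.0 * p * (1.0 - p)


def observed_heterozygosity(dosages) -> float:
    """Fraction of called genotypes that are heterozygous (dosage 1)."""
    d = _clean(dosages)
    return float((d == 1.0).mean())


def genotype_counts(dosages) -> tuple[int, int, int]:
    """(n0, n1, n2): called genotype counts by dosage class."""
    d = _clean(dosages)
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_test(dosages) -> float:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    Observed genotype counts are compared with expectations p^2, 2pq, q^2 at the
    sample allele frequency; no continuity correction. Returns the upper-tail
    p-value. Raises :class:`MonomorphicError` when only one allele is observed
    (the test is undefined).
    """
    n0, n1, n2 = genotype_counts(dosages)
    n = n0 + n1 + n2
    if n < 2:
        raise EmptyGenotypeError("need at least 2 called genotypes")
    p = (2 * n0 + n1) / (2.0 * n)
    if p in (0.0, 1.0):
        raise MonomorphicError("HWE test undefined for monomorphic SNP")
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_report(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP QC table for a subjects x SNPs dosage matrix.

    Returns columns ``snp_id, n_called, maf, het_obs, het_exp, hwe_p``; HWE p is
    NaN for monomorphic SNPs.
    """
    rows = []
    for snp in genotypes.columns:
        d = genotypes[snp].to_numpy(dtype=float)
        called = d[~np.isnan(d)]
        maf = minor_allele_frequency(d)
        try:
            hwe_p = hwe_test(d)
        except MonomorphicError:
            hwe_p = np.nan
        rows.append({
            "snp_id": snp,
            "n_called": int(called.size),
            "maf": maf,
            "het_obs": observed_heterozygosity(d),
            "het_exp": expected_heterozygosity(maf),
            "hwe_p": hwe_p,
        })
    return pd.DataFrame(rows)
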