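"""False-discovery-rate q-values for families of association tests.

Benjamini-Hochberg step-up q-values are the default engine; Storey's
pi0-adjusted estimator is optional (with 23-46 tests per family, pi0 estimation
is noisy, so it is never the default).
"""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def _validate(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return p


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = _validate(pvalues)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def estimate_pi0(pvalues, lambda_grid=None) -> float:
    """Storey estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)), averaged over the grid and
    clipped to (0, 1]. A degenerate estimate (<= 0) falls back to 1 with a
    warning.
    """
    p = _validate(pvalues)
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.95, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    estimates = [(p > l).mean() / (1.0 - l) for l in lam]
    pi0 = float(np.mean(estimates))
    if pi0 <= 0.0:
        log.warning("degenerate pi0 estimate %.3g; falling back to 1", pi0)
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(pvalues, lambda_grid=None, pi0: float | None = None) -> np.ndarray:
    """pi0-adjusted q-values: BH q-values scaled by the estimated null fraction.

    With ``pi0`` forced to 1 this reduces exactly to :func:`bh_qvalues`.
    """
    p = _validate(pvalues)
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    return np.minimum(bh_qvalues(p) * pi0, 1.0)
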