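"""Fisher-type combination of per-layer p-values, with and without
correlation correction.

Classical Fisher combines w independent p-values through
``T = -2 sum_i ln(p_i) ~ chi2_{2w}``.  Per-gene p-values from different
omics layers of the same subjects are *not* independent, so the corrected
(Omnibus) variant matches the first two moments of T to a scaled
chi-square ``c T ~ chi2_v`` (Satterthwaite):

    E(T)   = 2w
    Var(T) = 4w + 2 * sum_{i<j} cov(-2 ln p_i, -2 ln p_j)
    v = 2 E(T)^2 / Var(T),   c = v / E(T)

The covariance entries are estimated by perturbation (see
:mod:`omnifisher.perturbation`); the diagonal is fixed at 4, the exact
variance of ``-2 ln U`` for uniform U.  ``v`` is generally fractional, so
the chi-square survival function is evaluated at non-integer degrees of
freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import chi2

__all__ = ["CombineInput", "omnibus_fisher_combine", "usual_fisher_combine",
           "OmnibusWarning"]

P_LOG_FLOOR = 1e-300


class OmnibusWarning(UserWarning):
    """Signals a clamped variance or degenerate covariance input."""


def _check_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.maximum(p, P_LOG_FLOOR)


def _check_cov(cov, w: int) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (w, w):
        raise ValueError(f"covariance must be {w} x {w}")
    if not np.allclose(cov, cov.T, rtol=0, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    cov = 0.5 * (cov + cov.T)
    np.fill_diagonal(cov, 4.0)   # variance of -2 ln U, U ~ Uniform(0,1)
    return cov


class CombineInput:
    """p-values plus the covariance matrix of their -2 ln transforms."""

    def __init__(self, p_values, cov_matrix=None):
        self.p_values = _check_pvalues(p_values)
        w = self.p_values.size
        if cov_matrix is None:
            cov_matrix = 4.0 * np.eye(w)
        self.cov_matrix = _check_cov(cov_matrix, w)


def satterthwaite_params(cov: np.ndarray) -> tuple[float, float]:
    """(c, v) of the scaled chi-square matched to T's first two moments.

    Var(T) below a small positive floor (a tenth of the independence value
    4w) is clamped with a warning: heavily negative estimated covariances
    would otherwise produce an invalid or explosive v.
    """
    w = cov.shape[0]
    ET = 2.0 * w
    iu = np.triu_indices(w, k=1)
    var = 4.0 * w + 2.0 * float(np.sum(cov[iu]))
    if var <= 0.0:
        warnings.warn("estimated Var(T) <= 0; falling back to independence (4w)",
                      OmnibusWarning, stacklevel=3)
        var = 4.0 * w
    elif var < 0.1 * 4.0 * w:
        warnings.warn("estimated Var(T) clamped to 0.1 * 4w", OmnibusWarning,
                      stacklevel=3)
        var = 0.1 * 4.0 * w
    v = 2.0 * ET * ET / var
    c = v / ET
    return c, v


def _fisher_T(p: np.ndarray, axis=None) -> np.ndarray:
    return -2.0 * np.sum(np.log(p), axis=axis)


def omnibus_fisher_combine(p_values, cov_matrix=None) -> float:
    """Correlation-corrected Fisher combination of up to three p-values.

    With a zero off-diagonal covariance this reduces exactly to the
    classical Fisher combination (c = 1, v = 2w).
    """
    if isinstance(p_values, CombineInput):
        inp = p_values
    else:
        inp = CombineInput(p_values, cov_matrix)
    p = inp.p_values
    if p.size == 1:
        return float(p[0])
    c, v = satterthwaite_params(inp.cov_matrix)
    T = _fisher_T(p)
    return float(np.clip(chi2.sf(c * T, df=v), P_LOG_FLOOR, 1.0))


def omnibus_fisher_combine_batch(p_matrix: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Vectorised corrected combination: rows of ``p_matrix`` are draws.

    Shares the Satterthwaite (c, v) across draws, as the covariance is a
    property of the layer dependence, not of the individual draw.
    """
    p = np.maximum(np.asarray(p_matrix, dtype=float), P_LOG_FLOOR)
    if p.ndim != 2:
        raise ValueError("p_matrix must be draws x layers")
    if p.shape[1] == 1:
        return np.clip(p[:, 0], P_LOG_FLOOR, 1.0)
    c, v = satterthwaite_params(_check_cov(cov, p.shape[1]))
    T = _fisher_T(p, axis=1)
    return np.clip(chi2.sf(c * T, df=v), P_LOG_FLOOR, 1.0)


def usual_fisher_combine(p_values) -> float:
    """Classical Fisher combination assuming independent p-values."""
    p = _check_pvalues(p_values)
    if p.size == 1:
        return float(p[0])
    T = _fisher_T(p)
    return float(np.clip(chi2.sf(T, df=2 * p.size), P_LOG_FLOOR, 1.0))
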