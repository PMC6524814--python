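"""Covariates-only null models for continuous and binary traits.

The kernel-machine score test needs, from the null fit, the residual-like
vector, the error-variance or mean-variance weights, and the projection-like
matrix ``P0`` whose square root whitens feature matrices:

* gaussian:  ``beta = (X'X)^-1 X'y``; ``P0 = I - X(X'X)^-1 X'`` (an ordinary
  least-squares hat-complement, idempotent);
  ``sigma2 = ||y - X beta||^2 / (n - p)``.
* binomial:  logistic MLE by IRLS; ``Sigma = diag(mu (1 - mu))``;
  ``P0 = Sigma - Sigma X (X' Sigma X)^-1 X' Sigma``.

``P0`` is never materialised on the fast paths; :class:`NullModelFit` exposes
matrix-free products instead and builds the dense matrix only on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Phenotype", "NullModelFit", "fit_null", "read_phenotype", "read_covariates"]


class NullModelError(ValueError):
    """Raised when the covariates-only model cannot be fitted."""


@dataclass(frozen=True)
class Phenotype:
    """A trait vector with its family and subject identifiers.

    ``family`` is ``"gaussian"`` for continuous traits and ``"binomial"``
    for 0/1 disease status.
    """

    values: np.ndarray
    family: str
    subject_ids: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        ids = np.asarray(self.subject_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", ids)
        if values.ndim != 1 or values.size != ids.size:
            raise ValueError("phenotype values and subject_ids must be aligned 1-d arrays")
        if not np.all(np.isfinite(values)):
            raise ValueError("phenotype contains missing or non-finite values")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial":
            if not np.all(np.isin(values, (0.0, 1.0))):
                raise ValueError("binomial phenotype must be coded 0/1")
            if values.min() == values.max():
                raise NullModelError("binary phenotype has a single class; cannot fit")
        if pd.Index(ids).has_duplicates:
            raise ValueError("duplicate subject identifiers in phenotype")

    @property
    def n(self) -> int:
        return self.values.size

    @classmethod
    def infer(cls, values, subject_ids, family: str | None = None) -> "Phenotype":
        """Build a phenotype, inferring the family when not forced.

        Values contained in {0, 1} are treated as binomial unless
        ``family`` overrides the inference.
        """
        values = np.asarray(values, dtype=float)
        if family is None:
            family = "binomial" if np.all(np.isin(values, (0.0, 1.0))) else "gaussian"
        return cls(values=values, family=family, subject_ids=np.asarray(subject_ids))


def _check_design(X: np.ndarray, n: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"covariate rows ({X.shape[0]}) do not match phenotype length ({n})")
    # enforce an intercept column (every supported trait model has one)
    has_intercept = np.any(np.all(np.abs(X - X[0]) < 1e-12, axis=0) & (np.abs(X[0]) > 0))
    if not has_intercept:
        X = np.column_stack([np.ones(n), X])
    p = X.shape[1]
    if n < p + 2:
        raise NullModelError(f"need n >= p + 2 subjects (n={n}, p={p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns for the error message
        _, r = np.linalg.qr(X)
        bad = [j for j in range(p) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise NullModelError(f"rank-deficient covariate matrix (collinear columns {bad})")
    return X


@dataclass
class NullModelFit:
    """Fitted covariates-only model with the pieces the score test uses."""

    family: str
    subject_ids: np.ndarray
    X: np.ndarray
    beta_hat: np.ndarray
    residual: np.ndarray
    sigma2_hat: float | None = None        # gaussian only
    mu_hat: np.ndarray | None = None       # binomial only
    degenerate: bool = False               # gaussian perfect fit
    _xtx_inv: np.ndarray = field(default=None, repr=False)
    _sigma_diag: np.ndarray = field(default=None, repr=False)   # binomial mu(1-mu)
    _xsx_inv: np.ndarray = field(default=None, repr=False)      # (X' Sigma X)^-1

    #: materialise dense n x n matrices only below this size
    DENSE_CAP = 5000

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def sigma_hat_diag(self) -> np.ndarray:
        """Diagonal of Sigma-hat: ``sigma2 * 1`` (gaussian) or ``mu(1-mu)``."""
        if self.family == "gaussian":
            return np.full(self.n, self.sigma2_hat)
        return self._sigma_diag

    # -- matrix-free products ------------------------------------------------

    def p0_matmul(self, A: np.ndarray) -> np.ndarray:
        """``P0 @ A`` without forming P0."""
        A = np.asarray(A, dtype=float)
        squeeze = A.ndim == 1
        if squeeze:
            A = A[:, None]
        if A.shape[0] != self.n:
            raise ValueError("operand row dimension does not match the fit")
        if self.family == "gaussian":
            out = A - self.X @ (self._xtx_inv @ (self.X.T @ A))
        else:
            SA = self._sigma_diag[:, None] * A
            out = SA - self._sigma_diag[:, None] * (self.X @ (self._xsx_inv @ (self.X.T @ SA)))
        return out[:, 0] if squeeze else out

    def p0_half_matmul(self, A: np.ndarray) -> np.ndarray:
        """``P0^(1/2) @ A`` through a factorisation appropriate to the family.

        For the gaussian model P0 is idempotent, so the symmetric square
        root is P0 itself.  For the binomial model the symmetric root is
        obtained from a cached eigendecomposition of P0 (negative
        eigenvalues clamped to zero).
        """
        if self.family == "gaussian":
            return self.p0_matmul(A)
        root = self._symmetric_root()
        return root @ A

    def half_factor_matmul(self, A: np.ndarray) -> np.ndarray:
        """``F' @ A`` for a cheap factor ``F`` with ``F F' = P0``.

        For the binomial model ``F = Sigma^(1/2) (I - V V')`` with
        ``V = Sigma^(1/2) X (X' Sigma X)^(-1/2)``, applied in O(np) without
        any n x n decomposition.  ``F r`` has covariance ``P0`` for
        standard-normal ``r``, exactly like ``P0^(1/2) r``, so perturbation
        operators built from ``F`` have the correct joint law whenever all
        layers share this fit; with *different* subject sets per layer the
        symmetric root must be used instead.
        """
        if self.family == "gaussian":
            return self.p0_matmul(A)
        A = np.asarray(A, dtype=float)
        s_half = np.sqrt(self._sigma_diag)
        B = s_half[:, None] * A if A.ndim == 2 else s_half * A
        # project out the Sigma^(1/2) X column space (Z'Z = X' Sigma X)
        Z = s_half[:, None] * self.X
        return B - Z @ (self._xsx_inv @ (Z.T @ B))

    # -- dense forms (small n / verification) --------------------------------

    def p0_dense(self) -> np.ndarray:
        if self.n > self.DENSE_CAP:
            raise MemoryError(f"refusing to materialise P0 for n={self.n} > {self.DENSE_CAP}")
        return self.p0_matmul(np.eye(self.n))

    def _symmetric_root(self) -> np.ndarray:
        if not hasattr(self, "_root"):
            if self.n > self.DENSE_CAP:
                raise MemoryError(
                    f"symmetric P0^(1/2) needs a dense decomposition; n={self.n} exceeds cap"
                )
            P0 = self.p0_dense()
            w, V = np.linalg.eigh(0.5 * (P0 + P0.T))
            w = np.clip(w, 0.0, None)
            self._root = (V * np.sqrt(w)) @ V.T
        return self._root


def _fit_gaussian(y: np.ndarray, X: np.ndarray, ids: np.ndarray) -> NullModelFit:
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    degenerate = sigma2 <= np.finfo(float).eps * max(1.0, float(y @ y))
    return NullModelFit(
        family="gaussian", subject_ids=ids, X=X, beta_hat=beta, residual=resid,
        sigma2_hat=sigma2, degenerate=degenerate, _xtx_inv=xtx_inv,
    )


def _fit_binomial(y: np.ndarray, X: np.ndarray, ids: np.ndarray,
                  tol: float = 1e-8, max_iter: int = 50) -> NullModelFit:
    n, p = X.shape
    beta = np.zeros(p)
    # start from the intercept-only MLE
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.any(w < 1e-10):
            raise NullModelError("logistic separation: fitted probabilities at 0 or 1")
        z = eta + (y - mu) / w
        WX = w[:, None] * X
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    else:
        raise NullModelError(f"logistic IRLS did not converge in {max_iter} iterations")
    sigma_diag = mu * (1.0 - mu)
    xsx_inv = np.linalg.inv(X.T @ (sigma_diag[:, None] * X))
    return NullModelFit(
        family="binomial", subject_ids=ids, X=X, beta_hat=beta, residual=y - mu,
        mu_hat=mu, _sigma_diag=sigma_diag, _xsx_inv=xsx_inv,
    )


def fit_null(phenotype: Phenotype, covariates=None) -> NullModelFit:
    """Fit the covariates-only model for the phenotype's family.

    ``covariates`` is an n x p matrix; an intercept column is prepended if
    absent.  ``None`` fits an intercept-only model.
    """
    y = phenotype.values
    n = phenotype.n
    X = np.ones((n, 1)) if covariates is None else _check_design(covariates, n)
    if phenotype.family == "gaussian":
        return _fit_gaussian(y, X, phenotype.subject_ids)
    return _fit_binomial(y, X, phenotype.subject_ids)


# -- tabular input -----------------------------------------------------------

def read_phenotype(path, column: str | None = None, family: str | None = None) -> Phenotype:
    """Read a phenotype from a TSV keyed by subject ID in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate subject IDs in {path}")
    col = column or df.columns[0]
    series = df[col].dropna()
    return Phenotype.infer(series.to_numpy(dtype=float), series.index.to_numpy(), family=family)


def read_covariates(path) -> pd.DataFrame:
    """Read a covariate table (subject ID in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate subject IDs in {path}")
    return df.astype(float)
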