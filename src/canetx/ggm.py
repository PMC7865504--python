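"""Shrinkage Gaussian graphical model: partial correlations for p >> n.

The sample correlation matrix R is shrunk toward the identity with the
analytic (Schaefer-Strimmer) intensity

    lambda* = sum_{i!=j} Var_hat(r_ij) / sum_{i!=j} r_ij**2,  clamped to [0,1],

and partial correlations are read off the inverse of the shrunk matrix:
rho_ij = -omega_ij / sqrt(omega_ii * omega_jj) with Omega = (R*)^-1.
Shrinkage (lambda > 0) makes R* positive definite even when the number of
features exceeds the number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PartialCorrelationMatrix", "shrinkage_lambda", "partial_correlations"]

LAMBDA_FLOOR = 1e-8


@dataclass(frozen=True)
class PartialCorrelationMatrix:
    """Symmetric matrix of shrinkage partial correlations.

    ``rho`` has unit diagonal and entries in [-1, 1]; ``lam`` is the
    shrinkage intensity used; ``n`` the sample count.
    """

    rho: np.ndarray
    lam: float
    n: int

    def __post_init__(self):
        r = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", r)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rho must be square")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("rho must have unit diagonal")
        if np.nanmax(np.abs(r)) > 1 + 1e-8 or not np.isfinite(r).all():
            raise ValueError("partial correlations must be finite and within [-1, 1]")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be samples x features")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        bad = np.where(~np.isfinite(sd) | (sd == 0))[0]
        raise ValueError(f"zero-variance or non-finite columns at indices {bad.tolist()}")
    return (x - x.mean(axis=0)) / sd


def shrinkage_lambda(x: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    Uses the unbiased variance estimate of each sample correlation:
    with standardized columns and w_kij = x_ki * x_kj,

        r_ij      = n/(n-1) * mean_k(w_kij)
        Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - mean_k(w_kij))^2
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if p < 2:
        raise ValueError("need at least 2 features")
    xs = _standardize(x)
    # w has shape (n, p, p) conceptually; accumulate moments without 3-D blowup
    wbar = (xs.T @ xs) / n  # mean_k w_kij
    w2bar = (xs.T**2) @ (xs**2) / n  # mean_k w_kij^2
    sum_sq_dev = n * (w2bar - wbar**2)
    var_r = n / (n - 1.0) ** 3 * sum_sq_dev
    r = n / (n - 1.0) * wbar
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom == 0:
        return 1.0
    lam = np.sum(var_r[off]) / denom
    return float(min(1.0, max(0.0, lam)))


def partial_correlations(x: np.ndarray, *, lam: float | None = None) -> PartialCorrelationMatrix:
    """Estimate the shrinkage-GGM partial correlation matrix of ``x``.

    ``lam`` overrides the analytic intensity (used by resampling wrappers
    that want a fixed value); by default it is recomputed from ``x``.  A
    floor of 1e-8 is applied when features outnumber samples so the shrunk
    correlation matrix is invertible.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if p < 2:
        raise ValueError("need at least 2 features")
    if lam is None:
        lam = shrinkage_lambda(x)
    if p >= n and lam < LAMBDA_FLOOR:
        lam = LAMBDA_FLOOR
    xs = _standardize(x)
    r = (xs.T @ xs) / (n - 1.0)
    np.fill_diagonal(r, 1.0)
    r_star = lam * np.eye(p) + (1.0 - lam) * r
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "shrunk correlation matrix is singular; raise the shrinkage floor "
            "(collinear data at lambda = 0)"
        ) from None
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    return PartialCorrelationMatrix(rho=rho, lam=float(lam), n=n)
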