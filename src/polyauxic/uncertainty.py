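"""Parameter uncertainty from the curvature of the loss surface.

The Hessian of the residual sum of squares at the optimum is estimated by
central finite differences; the covariance matrix is the Moore-Penrose
pseudo-inverse of that Hessian scaled by the residual variance
RSS/(N-k).  Directions with singular values below the truncation threshold
are reported through the numerical rank rather than silently inflated.
Standard errors of the softmax-constrained phase weights are propagated
from the logit covariance with the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CovarianceBundle", "hessian_fd", "covariance", "delta_softmax"]

#: relative singular-value cutoff for the pseudo-inverse
RCOND = 1e-10


@dataclass
class CovarianceBundle:
    """Hessian, covariance, standard errors and the variance estimate."""

    H: np.ndarray
    C: np.ndarray
    se: np.ndarray
    sigma2: float
    rank: int


def _step(theta: np.ndarray) -> np.ndarray:
    return np.maximum(1e-5, 1e-4 * np.abs(theta))


def hessian_fd(loss, theta_hat) -> np.ndarray:
    """Second-order central-difference Hessian, symmetrized as (H+H^T)/2."""
    theta = np.asarray(theta_hat, dtype=float)
    m = theta.size
    h = _step(theta)
    f0 = loss(theta)
    if not np.isfinite(f0):
        raise ValueError("loss is non-finite at the expansion point")
    H = np.empty((m, m))
    # diagonal: (f(+h) - 2 f0 + f(-h)) / h^2
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        fp, fm = loss(theta + ei), loss(theta - ei)
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise ValueError(f"loss is non-finite on the stencil of parameter {i}")
        H[i, i] = (fp - 2.0 * f0 + fm) / (h[i] * h[i])
    # off-diagonal: four-point cross stencil
    for i in range(m):
        for j in range(i + 1, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = loss(theta + ei + ej)
            fpm = loss(theta + ei - ej)
            fmp = loss(theta - ei + ej)
            fmm = loss(theta - ei - ej)
            if not all(np.isfinite(v) for v in (fpp, fpm, fmp, fmm)):
                raise ValueError(
                    f"loss is non-finite on the stencil of parameters ({i}, {j})"
                )
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def covariance(H: np.ndarray, rss: float, n: int, k: int) -> CovarianceBundle:
    """Covariance C = sigma2 * H^+ with sigma2 = RSS/(N-k).

    The pseudo-inverse is computed by SVD with singular values below
    ``RCOND`` times the largest truncated; the returned rank counts the
    retained directions (parameters lost to truncation are unidentifiable
    at this optimum).
    """
    H = np.asarray(H, dtype=float)
    if n <= k:
        raise ValueError(f"need N > k for a variance estimate (N={n}, k={k})")
    sigma2 = rss / (n - k)
    u, s, vt = np.linalg.svd(0.5 * (H + H.T))
    cutoff = RCOND * (s[0] if s.size else 0.0)
    keep = s > cutoff
    sinv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    hplus = (vt.T * sinv) @ u.T
    C = sigma2 * 0.5 * (hplus + hplus.T)
    diag = np.clip(np.diag(C), 0.0, None)
    return CovarianceBundle(H=H, C=C, se=np.sqrt(diag), sigma2=sigma2,
                            rank=int(np.count_nonzero(keep)))


def delta_softmax(z_hat, C_z) -> np.ndarray:
    """Delta-method standard errors of softmax weights from logit covariance.

    With p = softmax(z), the Jacobian is J_jl = p_j * (delta_jl - p_l) and
    cov(p) = J C_z J^T; the returned vector is the square root of its
    diagonal.  Rows of cov(p) sum to zero because the weights are
    constrained to the simplex.
    """
    z = np.asarray(z_hat, dtype=float)
    C_z = np.asarray(C_z, dtype=float)
    n = z.size
    if C_z.shape != (n, n):
        raise ValueError(f"logit covariance must be {n}x{n}, got {C_z.shape}")
    e = np.exp(z - np.max(z))
    p = e / e.sum()
    J = np.diag(p) - np.outer(p, p)
    cov_p = J @ C_z @ J.T
    return np.sqrt(np.clip(np.diag(cov_p), 0.0, None))
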