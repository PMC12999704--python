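"""Loss and likelihood functions shared by the fitting pipeline.

The global search minimizes a smooth robust (Charbonnier) loss so gross
outliers cannot dominate; the final refinement minimizes the residual sum of
squares on the cleaned data, whose Gaussian log-likelihood feeds the
information criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Residuals", "rss", "charbonnier", "gaussian_loglik", "profiled_loglik"]

#: Default Charbonnier transition scale, in max-normalized response units.
#: The quadratic->linear crossover then sits at ~0.1% of the amplitude.
CHARBONNIER_EPS = 1e-3


@dataclass
class Residuals:
    """Observed-minus-predicted residuals with fit bookkeeping."""

    r: np.ndarray
    k: int
    n: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1:
            raise ValueError("residuals must be a 1-D array")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("residuals contain non-finite values")
        if self.n != self.r.size:
            raise ValueError("N must equal the number of residuals")


def _as_resid(residuals) -> np.ndarray:
    r = residuals.r if isinstance(residuals, Residuals) else np.asarray(residuals, float)
    if r.size == 0:
        raise ValueError("empty residual set")
    return r


def rss(residuals) -> float:
    """Residual sum of squares."""
    r = _as_resid(residuals)
    return float(np.dot(r, r))


def charbonnier(residuals, eps: float = CHARBONNIER_EPS) -> float:
    """Charbonnier robust loss: sum(sqrt(r^2 + eps^2) - eps).

    Quadratic (~r^2/(2*eps)) for |r| << eps and linear (~|r| - eps) in the
    tails, so large residuals are penalized linearly rather than
    quadratically.
    """
    if eps <= 0.0:
        raise ValueError("eps must be strictly positive")
    r = _as_resid(residuals)
    return float(np.sum(np.sqrt(r * r + eps * eps) - eps))


def gaussian_loglik(residuals, sigma: float) -> float:
    """Log-likelihood of i.i.d. Gaussian residuals with known scale sigma."""
    if sigma <= 0.0:
        raise ValueError("sigma must be strictly positive")
    r = _as_resid(residuals)
    n = r.size
    return -0.5 * n * math.log(2.0 * math.pi * sigma * sigma) - rss(r) / (
        2.0 * sigma * sigma
    )


def profiled_loglik(residuals) -> float:
    """Maximized Gaussian log-likelihood with the MLE variance RSS/N.

    Closed form: -N/2 * (ln(2*pi*RSS/N) + 1).  An all-zero residual vector
    has no finite maximized likelihood; +inf is returned as the supremum.
    """
    r = _as_resid(residuals)
    n = r.size
    s = rss(r)
    if s == 0.0:
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * s / n) + 1.0)
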