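"""ROUT-style outlier identification with false-discovery-rate control.

Residuals from a robust (Charbonnier) pre-fit are scaled by the robust
standard deviation of residuals (RSDR, the 68.27th percentile of the
absolute residuals with an N/(N-k) small-sample correction), converted to
two-tailed t-distribution p-values, and flagged by the Benjamini-Hochberg
step-up procedure at FDR level Q.  A single detection pass is made: pre-fit,
flag, then refit on the cleaned data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import TimeSeries

__all__ = ["OutlierReport", "robust_scale", "flag_outliers", "rout_pass"]

#: Default FDR level Q (fraction of flagged points expected to be false).
DEFAULT_Q = 0.01

_PCTL = 68.27


@dataclass
class OutlierReport:
    """Per-point outlier decisions and the statistics behind them."""

    mask: np.ndarray  # True where the point is flagged as an outlier
    q: float
    rsdr: float
    pvalues: np.ndarray
    excluded_indices: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.mask))

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "rsdr": self.rsdr,
            "n_flagged": self.n_flagged,
            "excluded_indices": [int(i) for i in self.excluded_indices],
            "pvalues": [float(p) for p in self.pvalues],
        }


def robust_scale(residuals, k: int) -> float:
    """Robust standard deviation of residuals.

    RSDR = P68.27(|r|) * N/(N-k); the percentile matches one Gaussian sigma
    and the factor corrects for the k parameters absorbed by the fit.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n <= k:
        raise ValueError(f"need more residuals ({n}) than parameters ({k})")
    return float(np.percentile(np.abs(r), _PCTL) * n / (n - k))


def flag_outliers(residuals, k: int, q: float = DEFAULT_Q) -> OutlierReport:
    """Flag residuals inconsistent with the fitted model at FDR level ``q``.

    Each residual is standardized by the RSDR, given a two-tailed p-value
    from a t distribution with N-k degrees of freedom, and the
    Benjamini-Hochberg step-up procedure selects the flagged set.
    Deterministic for a fixed input.
    """
    if not (0.0 <= q < 1.0):
        raise ValueError("FDR level q must be in [0, 1)")
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n <= k:
        raise ValueError(f"need more residuals ({n}) than parameters ({k})")
    rsdr = robust_scale(r, k)
    if rsdr == 0.0:
        if np.any(r != 0.0):
            raise ValueError("degenerate residual scale: RSDR is zero with nonzero residuals")
        pvalues = np.ones(n)
        mask = np.zeros(n, dtype=bool)
        return OutlierReport(mask, q, rsdr, pvalues, [])
    tstat = np.abs(r) / rsdr
    pvalues = 2.0 * stats.t.sf(tstat, df=n - k)
    mask = np.zeros(n, dtype=bool)
    if q > 0.0:
        order = np.argsort(pvalues)
        thresh = q * (np.arange(1, n + 1)) / n
        passed = pvalues[order] <= thresh
        if np.any(passed):
            last = np.max(np.nonzero(passed)[0])
            mask[order[: last + 1]] = True
    excluded = list(np.nonzero(mask)[0])
    return OutlierReport(mask, q, rsdr, pvalues, excluded)


def rout_pass(data: TimeSeries, family: str, n: int, options=None):
    """Single robust-regression-and-outlier-removal pass.

    Runs a Charbonnier pre-fit of an ``n``-phase model of the given family,
    flags points via :func:`flag_outliers`, and returns the cleaned series
    together with the full report (emitted even when empty).
    """
    # lazy import: the optimizer consumes this module for its own pipeline
    from .optimize import FitOptions, robust_prefit

    if options is None:
        options = FitOptions(family=family, n=n)
    k = 2 + 3 * n
    if len(data) <= k:
        raise ValueError(
            f"insufficient degrees of freedom: N={len(data)} <= k={k} (stage: rout)"
        )
    residuals = robust_prefit(data, options)
    report = flag_outliers(residuals, k=k, q=options.fdr_q)
    keep = ~report.mask
    if np.count_nonzero(keep) <= k:
        raise ValueError(
            "outlier removal left too few points for the requested model "
            f"(kept {int(np.count_nonzero(keep))}, k={k})"
        )
    return data.subset(keep), report
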