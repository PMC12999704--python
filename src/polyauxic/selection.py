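"""Information criteria and choice of the number of growth phases.

Each candidate phase count n is fitted with the full robust pipeline, the
appropriate criterion (AIC for large N/k ratios, AICc for small samples,
BIC for large N) is computed from the profiled Gaussian likelihood, and
the smallest n at the first local minimum of the criterion is selected;
on a plateau the smaller n wins (parsimony).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .models import TimeSeries
from .optimize import FitOptions, FitResult, fit

__all__ = [
    "SelectionRecord",
    "SelectionResult",
    "information_criterion",
    "choose_criterion",
    "select_n",
]

logger = logging.getLogger("polyauxic")

#: criterion values closer than this are treated as equal (plateau)
PLATEAU_TOL = 1e-6


@dataclass
class SelectionRecord:
    """One candidate phase count and its fitted criterion value."""

    n: int
    k: int
    fit: FitResult | None
    criterion_value: float
    error: str | None = None


@dataclass
class SelectionResult:
    """Outcome of the phase-count sweep."""

    records: list[SelectionRecord] = field(default_factory=list)
    criterion_used: str = "aicc"
    chosen_n: int = 0

    @property
    def best(self) -> FitResult:
        for rec in self.records:
            if rec.n == self.chosen_n and rec.fit is not None:
                return rec.fit
        raise LookupError("no fitted record for the chosen phase count")

    def to_dict(self) -> dict:
        return {
            "criterion_used": self.criterion_used,
            "chosen_n": self.chosen_n,
            "records": [
                {
                    "n": rec.n,
                    "k": rec.k,
                    "criterion_value": rec.criterion_value,
                    "rss": rec.fit.rss if rec.fit else math.nan,
                    "n_used": rec.fit.n_used if rec.fit else 0,
                    "outliers_removed": rec.fit.outliers.n_flagged if rec.fit else 0,
                    "error": rec.error,
                }
                for rec in self.records
            ],
            "best_fit": self.best.to_dict(),
        }


def information_criterion(loglik: float, k: int, n: int, which: str) -> float:
    """AIC, AICc or BIC from a maximized log-likelihood.

    AIC = 2k - 2 lnL;  AICc = AIC + 2k(k+1)/(N-k-1);  BIC = k lnN - 2 lnL.
    """
    if not math.isfinite(loglik):
        if loglik == -math.inf:
            return math.inf
        return -math.inf  # perfect interpolation: criterion unbounded below
    which = which.lower()
    if which == "aic":
        return 2.0 * k - 2.0 * loglik
    if which == "aicc":
        if n <= k + 1:
            raise ValueError(f"AICc undefined for N={n} <= k+1={k + 1}")
        return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)
    if which == "bic":
        return k * math.log(n) - 2.0 * loglik
    raise ValueError(f"unknown criterion {which!r}")


def choose_criterion(n: int, k: int) -> str:
    """Sample-size rule: AIC when N/k >= 40 and N <= 200, AICc when
    N/k < 40 and N <= 200, BIC when N > 200.

    At the N = 200 boundary with N/k < 40 the small-sample-safe AICc is
    kept.
    """
    if n <= 0 or k <= 0:
        raise ValueError("N and k must be positive")
    if n > 200:
        return "bic"
    if n / k >= 40:
        return "aic"
    return "aicc"


def select_n(
    data: TimeSeries,
    family: str,
    n_max: int,
    options: FitOptions | None = None,
    criterion: str = "auto",
    sweep_full: bool = False,
) -> SelectionResult:
    """Sweep the phase count and pick the first local criterion minimum.

    Stops at the first n whose successor does not improve the criterion
    (unless ``sweep_full``), skips counts with too few degrees of freedom,
    and keeps the best model's parameters across the sweep.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    base = options or FitOptions(family=family, n=1)
    N = len(data)
    crit = criterion.lower()
    if crit == "auto":
        crit = choose_criterion(N, 2 + 3 * 1)
    result = SelectionResult(criterion_used=crit)

    errors: list[str] = []
    for n in range(1, n_max + 1):
        k = 2 + 3 * n
        if N <= k + 1:
            logger.info("selection: stopping sweep at n=%d (N=%d <= k+1=%d)", n, N, k + 1)
            break
        opts = FitOptions(
            family=family,
            n=n,
            fix_yi=base.fix_yi,
            seed=base.seed,
            de_popsize=base.de_popsize,
            de_maxiter=base.de_maxiter,
            de_tol=base.de_tol,
            de_mutation=base.de_mutation,
            de_recombination=base.de_recombination,
            fdr_q=base.fdr_q,
            normalize=base.normalize,
            charbonnier_eps=base.charbonnier_eps,
            run_outliers=base.run_outliers,
        )
        try:
            fr = fit(data, opts)
            cval = information_criterion(fr.loglik, k, fr.n_used, crit)
            result.records.append(SelectionRecord(n=n, k=k, fit=fr, criterion_value=cval))
            logger.info("selection: n=%d %s=%.4f rss=%.4g", n, crit, cval, fr.rss)
        except ValueError as exc:
            errors.append(f"n={n}: {exc}")
            result.records.append(
                SelectionRecord(n=n, k=k, fit=None, criterion_value=math.nan, error=str(exc))
            )
            continue
        if not sweep_full and len(result.records) >= 2:
            prev = result.records[-2]
            if prev.fit is not None and cval >= prev.criterion_value - PLATEAU_TOL:
                break

    fitted = [rec for rec in result.records if rec.fit is not None]
    if not fitted:
        raise RuntimeError(
            "no phase count could be fitted; diagnostics: " + "; ".join(errors)
        )

    # first local minimum: the first n whose successor is not an improvement
    chosen = fitted[-1]
    for a, b in zip(fitted, fitted[1:]):
        if b.criterion_value >= a.criterion_value - PLATEAU_TOL:
            chosen = a
            break
    result.chosen_n = chosen.n
    return result
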