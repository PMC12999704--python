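"""Closed-form mono- and polyauxic growth models.

The central objects are reparameterized Boltzmann (logistic-type, symmetric)
and Gompertz (asymmetric) sigmoids expressed directly in terms of biologically
interpretable quantities: the asymptotes ``y_i`` and ``y_f``, the lag time
``lam`` (tangent-line construction at the inflection point) and the maximum
rate ``rmax`` (slope at the inflection point).  Polyauxic curves are weighted
sums of such sigmoids, one per growth phase, whose fractional amplitudes sum
to one and whose lag times are strictly ordered in time.

Decreasing curves (e.g. substrate depletion) are represented by the same
types with ``y_f < y_i``; the amplitude sign carries the direction while
``rmax`` stays strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeSeries",
    "PhaseParams",
    "KineticModel",
    "CanonicalBoltzmann",
    "CanonicalGompertz",
    "MonodParams",
    "eval_boltzmann",
    "eval_gompertz",
    "eval_polyauxic",
    "rate_polyauxic",
    "boltzmann_canonical_to_reparam",
    "boltzmann_reparam_to_canonical",
    "gompertz_canonical_to_reparam",
    "gompertz_reparam_to_canonical",
    "inflection_time",
    "eval_first_order",
    "mu_max_to_rmax",
    "rmax_to_mu_max",
    "fit_monod_saturation",
]

# |exponent| beyond this is clamped; exp(±700) brackets the double range.
_EXP_CLIP = 700.0

BOLTZMANN = "boltzmann"
GOMPERTZ = "gompertz"
FIRST_ORDER = "first_order"

_FAMILIES = (BOLTZMANN, GOMPERTZ, FIRST_ORDER)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeSeries:
    """Observed (time, response) points with optional replicate labels.

    Time must be finite and non-decreasing (strictly increasing within a
    replicate); at least 3 points are required for any downstream fit.
    """

    t: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1 or self.t.size != self.y.size:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size < 3:
            raise ValueError("a time series needs at least 3 points")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.y)):
            raise ValueError("time series contains non-finite values")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("time points must be non-decreasing")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.t.shape:
                raise ValueError("replicate labels must match the data length")
            for rep in np.unique(self.replicate):
                tr = self.t[self.replicate == rep]
                if np.any(np.diff(tr) <= 0):
                    raise ValueError(
                        f"time must be strictly increasing within replicate {rep!r}"
                    )

    def __len__(self) -> int:
        return self.t.size

    def subset(self, mask: np.ndarray) -> "TimeSeries":
        """Return a new series keeping only points where ``mask`` is True."""
        rep = self.replicate[mask] if self.replicate is not None else None
        return TimeSeries(self.t[mask], self.y[mask], rep, dict(self.meta))


@dataclass
class PhaseParams:
    """One growth phase: fractional amplitude, lag time and maximum rate."""

    p: float
    lam: float
    rmax: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"amplitude fraction p must be in (0, 1], got {self.p}")
        if self.rmax <= 0.0:
            raise ValueError(f"rmax must be strictly positive, got {self.rmax}")
        if self.lam < 0.0:
            raise ValueError(f"lag time must be non-negative, got {self.lam}")


@dataclass
class KineticModel:
    """A mono- or polyauxic kinetic model.

    ``phases`` is ordered by lag time; the fractional amplitudes sum to one
    so the composite spans exactly ``y_f - y_i``.
    """

    family: str
    yi: float
    yf: float
    phases: list[PhaseParams]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.phases:
            raise ValueError("a kinetic model needs at least one phase")
        psum = sum(ph.p for ph in self.phases)
        if abs(psum - 1.0) > 1e-8:
            raise ValueError(f"phase fractions must sum to 1, got {psum}")
        lams = [ph.lam for ph in self.phases]
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lag times must be strictly increasing across phases")
        if self.family == FIRST_ORDER:
            if len(self.phases) != 1 or self.yi != 0.0:
                raise ValueError("first-order model requires n=1 and yi=0")

    @property
    def n(self) -> int:
        return len(self.phases)

    @property
    def amplitude(self) -> float:
        return self.yf - self.yi

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "yi": self.yi,
            "yf": self.yf,
            "phases": [
                {"p": ph.p, "lam": ph.lam, "rmax": ph.rmax} for ph in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(
            family=d["family"],
            yi=float(d["yi"]),
            yf=float(d["yf"]),
            phases=[
                PhaseParams(float(p["p"]), float(p["lam"]), float(p["rmax"]))
                for p in d["phases"]
            ],
        )


@dataclass
class CanonicalBoltzmann:
    """Canonical Boltzmann sigmoid: y = yi + (yf-yi)/(1+exp((x0-x)/gamma))."""

    yi: float
    yf: float
    x0: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma == 0.0:
            raise ValueError("gamma must be nonzero")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        expo = np.clip((self.x0 - x) / self.gamma, -_EXP_CLIP, _EXP_CLIP)
        return self.yi + (self.yf - self.yi) / (1.0 + np.exp(expo))


@dataclass
class CanonicalGompertz:
    """Canonical Gompertz sigmoid: y = yi + (yf-yi)*exp(-b*exp(-c*x))."""

    yi: float
    yf: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b <= 0.0 or self.c <= 0.0:
            raise ValueError("b and c must be strictly positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        inner = np.clip(-self.c * x, -_EXP_CLIP, _EXP_CLIP)
        return self.yi + (self.yf - self.yi) * np.exp(-self.b * np.exp(inner))


@dataclass
class MonodParams:
    """Saturation kinetics r(S) = rstar * S / (km + S)."""

    rstar: float
    km: float

    def __post_init__(self) -> None:
        if self.rstar <= 0.0 or self.km <= 0.0:
            raise ValueError("rstar and km must be strictly positive")

    def rate(self, s):
        s = np.asarray(s, dtype=float)
        return self.rstar * s / (self.km + s)


# ---------------------------------------------------------------------------
# normalized single-phase terms
# ---------------------------------------------------------------------------


def _check_mono_args(yi: float, yf: float, rmax: float) -> None:
    for name, v in (("yi", yi), ("yf", yf), ("rmax", rmax)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if yf == yi:
        raise ValueError("degenerate amplitude: yf must differ from yi")
    if rmax <= 0.0:
        raise ValueError("rmax must be strictly positive")


def _boltzmann_unit(rnorm, lam, x):
    """Normalized Boltzmann term in [0, 1]; rnorm = rmax / |amplitude|."""
    expo = np.clip(4.0 * rnorm * (lam - x) + 2.0, -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(expo))


def _gompertz_unit(rnorm, lam, x):
    """Normalized Gompertz term in [0, 1]; rnorm = rmax / |amplitude|."""
    inner = np.clip(1.0 + rnorm * math.e * (lam - x), -_EXP_CLIP, _EXP_CLIP)
    return np.exp(-np.exp(inner))


_UNIT = {BOLTZMANN: _boltzmann_unit, GOMPERTZ: _gompertz_unit}


def eval_boltzmann(yi: float, yf: float, rmax: float, lam: float, x):
    """Reparameterized Boltzmann sigmoid y(x) = yi + A/(1+e^(4*rmax*(lam-x)/A+2)).

    ``rmax`` is the slope at the inflection point and ``lam`` the lag time
    from the tangent-line construction; A = yf - yi is the amplitude.
    """
    _check_mono_args(yi, yf, rmax)
    x = np.asarray(x, dtype=float)
    a = yf - yi
    return yi + a * _boltzmann_unit(rmax / abs(a), lam, x)


def eval_gompertz(yi: float, yf: float, rmax: float, lam: float, x):
    """Reparameterized Gompertz sigmoid y(x) = yi + A*exp(-exp(1+rmax*e*(lam-x)/A))."""
    _check_mono_args(yi, yf, rmax)
    x = np.asarray(x, dtype=float)
    a = yf - yi
    return yi + a * _gompertz_unit(rmax / abs(a), lam, x)


# ---------------------------------------------------------------------------
# polyauxic composition
# ---------------------------------------------------------------------------


def eval_polyauxic(model: KineticModel, x):
    """Evaluate a polyauxic model: y(x) = yi + A * sum_j p_j * f_j(x).

    Each phase is a normalized sigmoid whose effective amplitude is
    A * p_j and whose maximum rate is the phase's own ``rmax``.
    With a single phase this reduces exactly to the monoauxic forms.
    """
    if model.family == FIRST_ORDER:
        return eval_first_order(model.yf, model.phases[0].rmax, x)
    x = np.asarray(x, dtype=float)
    a = model.amplitude
    if a == 0.0:
        raise ValueError("degenerate amplitude: yf must differ from yi")
    unit = _UNIT[model.family]
    total = np.zeros_like(x, dtype=float)
    for ph in model.phases:
        total += ph.p * unit(ph.rmax / (abs(a) * ph.p), ph.lam, x)
    return model.yi + a * total


def rate_polyauxic(model: KineticModel, x):
    """Analytic first derivative dy/dx of the polyauxic composite."""
    x = np.asarray(x, dtype=float)
    if model.family == FIRST_ORDER:
        r1 = model.phases[0].rmax
        return model.yf * r1 * np.exp(-r1 * np.clip(x, 0.0, None))
    a = model.amplitude
    sign = 1.0 if a > 0 else -1.0
    total = np.zeros_like(x, dtype=float)
    for ph in model.phases:
        rnorm = ph.rmax / (abs(a) * ph.p)
        if model.family == BOLTZMANN:
            u = _boltzmann_unit(rnorm, ph.lam, x)
            total += 4.0 * ph.rmax * u * (1.0 - u)
        else:
            inner = np.clip(1.0 + rnorm * math.e * (ph.lam - x), -_EXP_CLIP, _EXP_CLIP)
            g = np.exp(inner)
            total += ph.rmax * math.e * np.exp(-g) * g
    return sign * total


# ---------------------------------------------------------------------------
# canonical <-> reparameterized conversions
# ---------------------------------------------------------------------------


def boltzmann_canonical_to_reparam(cb: CanonicalBoltzmann) -> tuple[float, float]:
    """Map (x0, gamma) to (rmax, lam): rmax = A/(4*gamma), lam = x0 - 2*gamma."""
    if cb.gamma <= 0.0:
        raise ValueError("gamma must be positive for an increasing-in-x sigmoid")
    rmax = (cb.yf - cb.yi) / (4.0 * cb.gamma)
    lam = cb.x0 - 2.0 * cb.gamma
    return rmax, lam


def boltzmann_reparam_to_canonical(
    yi: float, yf: float, rmax: float, lam: float
) -> CanonicalBoltzmann:
    """Inverse map: gamma = A/(4*rmax), x0 = lam + A/(2*rmax)."""
    _check_mono_args(yi, yf, rmax)
    gamma = (yf - yi) / (4.0 * rmax)
    x0 = lam + (yf - yi) / (2.0 * rmax)
    return CanonicalBoltzmann(yi, yf, x0, gamma)


def gompertz_canonical_to_reparam(cg: CanonicalGompertz) -> tuple[float, float]:
    """Map (b, c) to (rmax, lam): rmax = A*c/e, lam = (ln b - 1)/c."""
    rmax = (cg.yf - cg.yi) * cg.c / math.e
    lam = (math.log(cg.b) - 1.0) / cg.c
    return rmax, lam


def gompertz_reparam_to_canonical(
    yi: float, yf: float, rmax: float, lam: float
) -> CanonicalGompertz:
    """Inverse map: c = rmax*e/A, b = exp(1 + lam*rmax*e/A)."""
    _check_mono_args(yi, yf, rmax)
    a = yf - yi
    c = rmax * math.e / a
    b = math.exp(1.0 + lam * rmax * math.e / a)
    return CanonicalGompertz(yi, yf, b, c)


def inflection_time(family: str, yi: float, yf: float, rmax: float, lam: float) -> float:
    """Abscissa of the maximum rate, derived from (rmax, lam).

    Boltzmann: lam + A/(2*rmax); Gompertz: lam + A/(rmax*e), with A = |yf-yi|.
    """
    _check_mono_args(yi, yf, rmax)
    a = abs(yf - yi)
    if family == BOLTZMANN:
        return lam + a / (2.0 * rmax)
    if family == GOMPERTZ:
        return lam + a / (rmax * math.e)
    raise ValueError(f"no inflection for family {family!r}")


# ---------------------------------------------------------------------------
# first-order (no lag) model
# ---------------------------------------------------------------------------


def eval_first_order(yf: float, r1: float, t):
    """First-order cumulative model y = yf*(1 - exp(-r1*t)); y(0) = 0."""
    if yf <= 0.0 or r1 <= 0.0:
        raise ValueError("yf and r1 must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time is not allowed for the first-order model")
    return yf * (1.0 - np.exp(-np.clip(r1 * t, None, _EXP_CLIP)))


# ---------------------------------------------------------------------------
# specific-growth-rate conversions
# ---------------------------------------------------------------------------


def mu_max_to_rmax(family: str, mu_app: float, xi: float, xf: float) -> float:
    """Convert an apparent maximum specific growth rate to the curve rmax.

    The conversion evaluates mu = (1/X)*dX/dt at the inflection point, where
    the biomass equals (Xi+Xf)/2 for the symmetric Boltzmann curve and
    Xi + (Xf-Xi)/e for the Gompertz curve.
    """
    if mu_app <= 0.0:
        raise ValueError("mu_app must be strictly positive")
    if xf <= xi or xi < 0.0:
        raise ValueError("degenerate amplitude: need Xf > Xi >= 0")
    if family == BOLTZMANN:
        # X at inflection is (Xi+Xf)/2 but the net conversion collapses to A/2
        return mu_app * (xf - xi) / 2.0
    if family == GOMPERTZ:
        return mu_app * (xi + (xf - xi) / math.e)
    raise ValueError(f"no specific-rate conversion for family {family!r}")


def rmax_to_mu_max(family: str, rmax: float, xi: float, xf: float) -> float:
    """Inverse of :func:`mu_max_to_rmax`."""
    if rmax <= 0.0:
        raise ValueError("rmax must be strictly positive")
    if xf <= xi or xi < 0.0:
        raise ValueError("degenerate amplitude: need Xf > Xi >= 0")
    if family == BOLTZMANN:
        return 2.0 * rmax / (xf - xi)
    if family == GOMPERTZ:
        return rmax / (xi + (xf - xi) / math.e)
    raise ValueError(f"no specific-rate conversion for family {family!r}")


# ---------------------------------------------------------------------------
# Monod saturation fit
# ---------------------------------------------------------------------------


def fit_monod_saturation(s, r_app) -> MonodParams:
    """Least-squares fit of apparent maximum rates vs. initial substrate.

    Fits r_app = rstar * S / (km + S); ``rstar`` is the saturating-limit
    maximum rate and ``km`` the half-saturation constant.
    """
    s = np.asarray(s, dtype=float)
    r_app = np.asarray(r_app, dtype=float)
    if s.size != r_app.size:
        raise ValueError("s and r_app must have the same length")
    if np.unique(s).size < 3:
        raise ValueError("need at least 3 distinct substrate levels")
    if np.any(s <= 0) or np.any(r_app <= 0):
        raise ValueError("substrate levels and rates must be strictly positive")

    def monod(si, rstar, km):
        return rstar * si / (km + si)

    p0 = (float(r_app.max()) * 1.5, float(np.median(s)))
    try:
        popt, _ = curve_fit(
            monod, s, r_app, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological designs
        raise RuntimeError(f"Monod saturation fit failed to converge: {exc}") from exc
    return MonodParams(rstar=float(popt[0]), km=float(popt[1]))
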