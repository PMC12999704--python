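"""Constraint encoding and the global->local fitting pipeline.

The polyauxic constraint set (weights on the simplex, strictly positive
rates, chronologically ordered lags) is enforced structurally by an
unconstrained latent encoding: softmax logits for the weights (gauge fixed
by z_n = 0), a non-negative first lag plus log-increments for the later
lags, and log rates.  Any point of the box-bounded latent space therefore
decodes to a valid model, which keeps the Differential Evolution search
space simple.

Pipeline (one call to :func:`fit`):

1. normalize time and response by their maxima;
2. heuristic initialization from derivative peaks;
3. Differential Evolution global search under the Charbonnier robust loss;
4. single ROUT outlier pass on the robust residuals;
5. L-BFGS-B refinement minimizing RSS on the cleaned data;
6. Hessian-based uncertainty and de-normalization back to input units.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize
from scipy.signal import find_peaks, peak_widths

from . import objectives
from .models import (
    BOLTZMANN,
    GOMPERTZ,
    KineticModel,
    PhaseParams,
    TimeSeries,
)
from .outliers import DEFAULT_Q, OutlierReport, flag_outliers
from .uncertainty import covariance, delta_softmax, hessian_fd

__all__ = [
    "LatentVector",
    "FitOptions",
    "FitResult",
    "encode",
    "decode",
    "heuristic_init",
    "fit_global",
    "fit_local",
    "robust_prefit",
    "fit",
]

logger = logging.getLogger("polyauxic")

_LOG_R_LO, _LOG_R_HI = math.log(1e-3), math.log(1e3)
_LOG_G_LO, _LOG_G_HI = math.log(1e-3), 0.0
_Z_LO, _Z_HI = -10.0, 10.0
_R_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# latent encoding
# ---------------------------------------------------------------------------


@dataclass
class LatentVector:
    """Unconstrained optimizer-space encoding of a kinetic model.

    ``z`` holds the n softmax logits with the last fixed to zero (gauge);
    lags are ``lam1`` plus cumulative ``exp(g)`` increments; rates are
    stored as logs.  ``yi`` is None when the initial asymptote is fixed
    to zero.
    """

    family: str
    yi: float | None
    yf: float
    z: np.ndarray  # length n, z[-1] == 0
    lam1: float
    g: np.ndarray  # length n-1
    logr: np.ndarray  # length n

    def __post_init__(self) -> None:
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float)) if np.size(self.g) else np.empty(0)
        self.logr = np.atleast_1d(np.asarray(self.logr, dtype=float))
        n = self.logr.size
        if self.z.size != n or self.g.size != n - 1:
            raise ValueError("inconsistent latent block sizes")
        if abs(self.z[-1]) > 1e-12:
            raise ValueError("softmax gauge requires the last logit to be zero")

    @property
    def n(self) -> int:
        return self.logr.size

    @property
    def fix_yi(self) -> bool:
        return self.yi is None

    def to_free(self) -> np.ndarray:
        head = [] if self.fix_yi else [self.yi]
        return np.concatenate(
            [head, [self.yf], self.z[:-1], [self.lam1], self.g, self.logr]
        )

    @classmethod
    def from_free(cls, theta: np.ndarray, family: str, n: int, fix_yi: bool) -> "LatentVector":
        theta = np.asarray(theta, dtype=float)
        if theta.size != free_dim(n, fix_yi):
            raise ValueError(
                f"latent vector length {theta.size} does not match n={n}, fix_yi={fix_yi}"
            )
        i = 0
        yi = None
        if not fix_yi:
            yi = float(theta[0])
            i = 1
        yf = float(theta[i]); i += 1
        z = np.concatenate([theta[i : i + n - 1], [0.0]]); i += n - 1
        lam1 = float(theta[i]); i += 1
        g = theta[i : i + n - 1]; i += n - 1
        logr = theta[i : i + n]
        return cls(family, yi, yf, z, lam1, g, logr)


def free_dim(n: int, fix_yi: bool) -> int:
    """Dimension of the free optimizer vector (softmax gauge removes one logit)."""
    return (0 if fix_yi else 1) + 1 + (n - 1) + 1 + (n - 1) + n


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = np.asarray(z, dtype=float)
    zs = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(zs)
    return e / np.sum(e, axis=-1, keepdims=True)


def decode(latent: LatentVector) -> KineticModel:
    """Map a latent vector to the kinetic model it encodes."""
    p = softmax(latent.z)
    lams = latent.lam1 + np.concatenate([[0.0], np.cumsum(np.exp(latent.g))])
    rates = np.exp(latent.logr)
    yi = 0.0 if latent.fix_yi else latent.yi
    phases = [
        PhaseParams(float(p[j]), float(lams[j]), float(rates[j]))
        for j in range(latent.n)
    ]
    return KineticModel(latent.family, yi, latent.yf, phases)


def encode(model: KineticModel, fix_yi: bool = False) -> LatentVector:
    """Inverse of :func:`decode`; exact up to floating point."""
    n = model.n
    p = np.array([ph.p for ph in model.phases])
    z = np.log(p) - np.log(p[-1])
    lams = np.array([ph.lam for ph in model.phases])
    g = np.log(np.diff(lams)) if n > 1 else np.empty(0)
    logr = np.log([ph.rmax for ph in model.phases])
    if fix_yi and model.yi != 0.0:
        raise ValueError("cannot fix yi=0 for a model with nonzero yi")
    return LatentVector(
        family=model.family,
        yi=None if fix_yi else model.yi,
        yf=model.yf,
        z=z,
        lam1=float(lams[0]),
        g=g,
        logr=logr,
    )


# ---------------------------------------------------------------------------
# options / result containers
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Controls for one fit. A set seed makes the whole run reproducible."""

    family: str = GOMPERTZ
    n: int = 1
    fix_yi: bool = False
    seed: int | None = None
    de_popsize: int = 15          # population multiplier (total = popsize * dim)
    de_maxiter: int = 1000
    de_tol: float = 1e-8
    de_mutation: tuple = (0.5, 1.0)
    de_recombination: float = 0.7
    fdr_q: float = DEFAULT_Q
    normalize: bool = True
    charbonnier_eps: float = objectives.CHARBONNIER_EPS
    run_outliers: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.family not in (BOLTZMANN, GOMPERTZ):
            raise ValueError(f"cannot fit family {self.family!r} with the sigmoid pipeline")

    @property
    def k(self) -> int:
        """Parameter count charged by the information criteria: k = 2 + 3n."""
        return 2 + 3 * self.n

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n": self.n,
            "fix_yi": self.fix_yi,
            "seed": self.seed,
            "de_popsize": self.de_popsize,
            "de_maxiter": self.de_maxiter,
            "de_tol": self.de_tol,
            "de_mutation": list(self.de_mutation),
            "de_recombination": self.de_recombination,
            "fdr_q": self.fdr_q,
            "normalize": self.normalize,
            "charbonnier_eps": self.charbonnier_eps,
        }


@dataclass
class FitResult:
    """A fitted model with residual statistics and uncertainty."""

    model: KineticModel
    theta_hat: LatentVector
    rss: float
    loglik: float
    ic: dict
    outliers: OutlierReport
    se: dict
    cov: np.ndarray | None
    n_used: int
    converged: bool
    provenance: dict
    r2: float = math.nan

    @property
    def k(self) -> int:
        return 2 + 3 * self.model.n

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "rss": self.rss,
            "loglik": self.loglik,
            "r2": self.r2,
            "ic": dict(self.ic),
            "k": self.k,
            "n_used": self.n_used,
            "converged": self.converged,
            "se": {key: _jsonify(val) for key, val in self.se.items()},
            "outliers": self.outliers.to_dict(),
            "provenance": dict(self.provenance),
        }


def _jsonify(v):
    if isinstance(v, np.ndarray):
        return [float(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# vectorized prediction in latent space
# ---------------------------------------------------------------------------


def _predict_free(theta: np.ndarray, t: np.ndarray, family: str, n: int, fix_yi: bool):
    """Model prediction for one candidate (dim,) or a batch (S, dim).

    Returns shape (N,) for a single candidate or (S, N) for a batch.
    """
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    th = theta[None, :] if single else theta
    i = 0
    if fix_yi:
        yi = np.zeros((th.shape[0], 1))
    else:
        yi = th[:, :1]
        i = 1
    yf = th[:, i : i + 1]; i += 1
    z = np.concatenate([th[:, i : i + n - 1], np.zeros((th.shape[0], 1))], axis=1)
    i += n - 1
    lam1 = th[:, i : i + 1]; i += 1
    g = th[:, i : i + n - 1]; i += n - 1
    logr = th[:, i : i + n]

    p = softmax(z)                                    # (S, n)
    incr = np.exp(g)
    lams = lam1 + np.concatenate(
        [np.zeros((th.shape[0], 1)), np.cumsum(incr, axis=1)], axis=1
    )                                                 # (S, n)
    rates = np.exp(logr)                              # (S, n)
    amp = yf - yi                                     # (S, 1)
    absamp = np.maximum(np.abs(amp), 1e-12)

    # (S, n, N) broadcast of the normalized per-phase sigmoid
    rnorm = rates / (absamp * p)                      # (S, n)
    arg = (lams[:, :, None] - t[None, None, :]) * rnorm[:, :, None]
    if family == BOLTZMANN:
        expo = np.clip(4.0 * arg + 2.0, -700.0, 700.0)
        unit = 1.0 / (1.0 + np.exp(expo))
    else:
        inner = np.clip(1.0 + math.e * arg, -700.0, 700.0)
        unit = np.exp(-np.exp(inner))
    y = yi + amp * np.sum(p[:, :, None] * unit, axis=1)
    return y[0] if single else y


def _charbonnier_objective(t, y, family, n, fix_yi, eps):
    def loss(theta):
        theta = np.asarray(theta, dtype=float)
        if theta.ndim == 2:  # vectorized DE passes (dim, S)
            pred = _predict_free(theta.T, t, family, n, fix_yi)
            r = pred - y[None, :]
            return np.sum(np.sqrt(r * r + eps * eps) - eps, axis=1)
        r = _predict_free(theta, t, family, n, fix_yi) - y
        return float(np.sum(np.sqrt(r * r + eps * eps) - eps))

    return loss


def _rss_objective(t, y, family, n, fix_yi):
    def loss(theta):
        r = _predict_free(np.asarray(theta, float), t, family, n, fix_yi) - y
        return float(np.dot(r, r))

    return loss


def _bounds(n: int, fix_yi: bool) -> list[tuple[float, float]]:
    """Box bounds on the free latent vector, in normalized data units."""
    b: list[tuple[float, float]] = []
    if not fix_yi:
        b.append((-0.5, 0.5))
    b.append((0.5, 1.5))                       # yf
    b += [(_Z_LO, _Z_HI)] * (n - 1)            # softmax logits
    b.append((0.0, 1.0))                       # lam1
    b += [(_LOG_G_LO, _LOG_G_HI)] * (n - 1)    # log lag increments
    b += [(_LOG_R_LO, _LOG_R_HI)] * n          # log rates
    return b


# ---------------------------------------------------------------------------
# heuristic initialization
# ---------------------------------------------------------------------------


def _moving_average(y: np.ndarray, window: int = 5) -> np.ndarray:
    window = min(window, y.size)
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def heuristic_init(
    data: TimeSeries,
    n: int,
    fix_yi: bool = False,
    popsize: int = 15,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Derivative-peak seeded DE population (normalized data expected).

    The response is smoothed with a 5-point moving average, differentiated,
    and up to ``n`` local maxima of the derivative are located by prominence;
    these approximate the phase inflection points.  Lags are seeded half a
    peak-width before each peak, rates from the peak heights and weights from
    the amplitude partition between peaks.  The remaining population members
    are jittered copies plus uniform draws inside the bounds.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(data) < 3:
        raise ValueError("need at least 3 points for initialization")
    t, y = data.t, data.y
    bounds = np.array(_bounds(n, fix_yi))
    dim = bounds.shape[0]
    size = max(popsize * dim, 5)
    lo, hi = bounds[:, 0], bounds[:, 1]
    uniform = rng.uniform(lo, hi, size=(size, dim))

    ys = _moving_average(y, 5)
    dy = np.gradient(ys, t)
    if np.all(np.abs(dy) < 1e-12):
        warnings.warn("flat signal: falling back to uniform random initialization")
        return uniform

    peaks, props = find_peaks(dy, prominence=0.05 * max(np.max(np.abs(dy)), 1e-12))
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dy))])
    order = np.argsort(props["prominences"])[::-1] if peaks.size > 1 and "prominences" in props else np.arange(peaks.size)
    chosen = np.sort(peaks[order[:n]])
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0

    try:
        widths = peak_widths(dy, chosen, rel_height=0.5)[0] * np.median(np.diff(t))
    except ValueError:
        widths = np.full(chosen.size, 0.1 * span)
    widths = np.where(np.isfinite(widths) & (widths > 0), widths, 0.1 * span)

    lam_seed = np.clip(t[chosen] - 0.5 * widths, 0.0, None)
    r_seed = np.clip(dy[chosen], 1e-3, 1e3)

    # amplitude partition at midpoints between consecutive peaks
    edges = np.concatenate([[t[0]], (t[chosen][1:] + t[chosen][:-1]) / 2.0, [t[-1]]])
    yedge = np.interp(edges, t, ys)
    p_seed = np.clip(np.diff(yedge), 0.02, None)
    p_seed = p_seed / p_seed.sum()

    if chosen.size < n:  # pad missing phases after the last detected one
        miss = n - chosen.size
        extra_lam = lam_seed[-1] + span * (np.arange(1, miss + 1)) / (n + 1)
        lam_seed = np.concatenate([lam_seed, extra_lam])
        r_seed = np.concatenate([r_seed, np.full(miss, np.median(r_seed))])
        p_seed = np.concatenate([p_seed * chosen.size / n, np.full(miss, 1.0 / n)])
        p_seed = p_seed / p_seed.sum()

    lam_seed = np.sort(lam_seed)
    lam_seed += np.arange(n) * 1e-6  # break exact ties
    increments = np.clip(np.diff(lam_seed), math.exp(_LOG_G_LO) * 1.01, math.exp(_LOG_G_HI))

    head = [] if fix_yi else [float(y[0])]
    base = np.concatenate(
        [
            head,
            [float(y[-1])],
            np.log(p_seed[:-1] / p_seed[-1]) if n > 1 else [],
            [float(lam_seed[0])],
            np.log(increments) if n > 1 else [],
            np.log(r_seed),
        ]
    )
    base = np.clip(base, lo, hi)

    n_seeded = max(size // 2, 1)
    jitter = rng.normal(scale=0.1 * (hi - lo), size=(n_seeded, dim))
    seeded = np.clip(base[None, :] + jitter, lo, hi)
    seeded[0] = base
    pop = np.vstack([seeded, uniform[n_seeded:]])
    return pop[:size]


# ---------------------------------------------------------------------------
# global and local stages
# ---------------------------------------------------------------------------


def fit_global(
    data: TimeSeries,
    options: FitOptions,
    init: np.ndarray | None = None,
) -> tuple[LatentVector, bool]:
    """Differential Evolution search minimizing the Charbonnier loss.

    Deterministic for a fixed ``options.seed``.  Returns the best latent
    vector and a convergence flag (best-so-far is returned either way).
    """
    n, fix_yi = options.n, options.fix_yi
    rng = np.random.default_rng(options.seed)
    if init is None:
        init = heuristic_init(data, n, fix_yi, options.de_popsize, rng)
    loss = _charbonnier_objective(
        data.t, data.y, options.family, n, fix_yi, options.charbonnier_eps
    )
    result = differential_evolution(
        loss,
        bounds=_bounds(n, fix_yi),
        strategy="randtobest1bin",
        init=init,
        popsize=options.de_popsize,
        maxiter=options.de_maxiter,
        tol=options.de_tol,
        mutation=options.de_mutation,
        recombination=options.de_recombination,
        seed=rng,
        polish=False,
        vectorized=True,
        updating="deferred",
    )
    latent = LatentVector.from_free(result.x, options.family, n, fix_yi)
    return latent, bool(result.success)


def fit_local(
    data: TimeSeries,
    start: LatentVector,
    options: FitOptions,
    loss: str = "rss",
) -> LatentVector:
    """Bounded L-BFGS-B refinement from ``start``; never worsens the loss."""
    n, fix_yi = options.n, options.fix_yi
    x0 = start.to_free()
    if loss == "rss":
        fun = _rss_objective(data.t, data.y, options.family, n, fix_yi)
    elif loss == "charbonnier":
        fun = _charbonnier_objective(
            data.t, data.y, options.family, n, fix_yi, options.charbonnier_eps
        )
    else:
        raise ValueError(f"unknown loss {loss!r}")
    res = minimize(fun, x0, method="L-BFGS-B", bounds=_bounds(n, fix_yi))
    if not res.success:
        logger.debug("local refinement stopped early: %s", res.message)
    if fun(res.x) <= fun(x0):
        return LatentVector.from_free(res.x, options.family, n, fix_yi)
    return start


# ---------------------------------------------------------------------------
# normalization helpers
# ---------------------------------------------------------------------------


def _normalize(data: TimeSeries, options: FitOptions):
    """Return (working series, t_scale, y_scale, reflection constant).

    A decreasing series (overall negative trend) is reflected to
    ``c - y`` with ``c = max(y) + min(y)`` so the fit always sees an
    increasing curve; the reflection constant is carried for the inverse
    map (None when no reflection was applied).
    """
    t, y = data.t.copy(), data.y.copy()
    slope = np.polyfit(t, y, 1)[0] if np.ptp(t) > 0 else 0.0
    reflect_c = None
    if slope < 0:
        reflect_c = float(y.max() + y.min())
        y = reflect_c - y
    if options.normalize:
        t_scale = float(np.max(np.abs(t))) or 1.0
        y_scale = float(np.max(np.abs(y))) or 1.0
    else:
        t_scale = y_scale = 1.0
    work = TimeSeries(t / t_scale, y / y_scale, data.replicate, dict(data.meta))
    return work, t_scale, y_scale, reflect_c


def _denormalize_model(
    model: KineticModel, t_scale: float, y_scale: float, reflect_c: float | None
) -> KineticModel:
    phases = [
        PhaseParams(ph.p, ph.lam * t_scale, ph.rmax * y_scale / t_scale)
        for ph in model.phases
    ]
    yi, yf = model.yi * y_scale, model.yf * y_scale
    if reflect_c is not None:
        yi, yf = reflect_c - yi, reflect_c - yf
    return KineticModel(model.family, yi, yf, phases)


# ---------------------------------------------------------------------------
# robust pre-fit (shared with the ROUT pass)
# ---------------------------------------------------------------------------


def robust_prefit(data: TimeSeries, options: FitOptions) -> np.ndarray:
    """Charbonnier-loss pre-fit; returns residuals in input units."""
    work, t_scale, y_scale, _ = _normalize(data, options)
    latent, _ = fit_global(work, options)
    latent = fit_local(work, latent, options, loss="charbonnier")
    pred = _predict_free(latent.to_free(), work.t, options.family, options.n, options.fix_yi)
    return (work.y - pred) * y_scale


# ---------------------------------------------------------------------------
# natural-parameter reporting vector for the Hessian
# ---------------------------------------------------------------------------


def _natural_vector(latent: LatentVector) -> np.ndarray:
    model = decode(latent)
    head = [] if latent.fix_yi else [model.yi]
    return np.concatenate(
        [
            head,
            [model.yf],
            latent.z[:-1],
            [ph.lam for ph in model.phases],
            [ph.rmax for ph in model.phases],
        ]
    )


def _natural_rss_fn(t, y, family, n, fix_yi):
    """RSS as a function of [yi?, yf, z_1..z_{n-1}, lam_1..n, r_1..n]."""

    def fun(theta):
        theta = np.asarray(theta, dtype=float)
        i = 0
        yi = 0.0
        if not fix_yi:
            yi = theta[0]
            i = 1
        yf = theta[i]; i += 1
        z = np.concatenate([theta[i : i + n - 1], [0.0]]); i += n - 1
        lams = theta[i : i + n]; i += n
        rates = np.maximum(theta[i : i + n], _R_FLOOR)
        p = softmax(z)
        amp = yf - yi
        absamp = max(abs(amp), 1e-12)
        total = np.zeros_like(t)
        for j in range(n):
            rnorm = rates[j] / (absamp * p[j])
            arg = (lams[j] - t) * rnorm
            if family == BOLTZMANN:
                unit = 1.0 / (1.0 + np.exp(np.clip(4.0 * arg + 2.0, -700, 700)))
            else:
                unit = np.exp(-np.exp(np.clip(1.0 + math.e * arg, -700, 700)))
            total += p[j] * unit
        r = yi + amp * total - y
        return float(np.dot(r, r))

    return fun


def _parameter_names(n: int, fix_yi: bool) -> list[str]:
    names = [] if fix_yi else ["yi"]
    names.append("yf")
    names += [f"z{j + 1}" for j in range(n - 1)]
    names += [f"lam{j + 1}" for j in range(n)]
    names += [f"rmax{j + 1}" for j in range(n)]
    return names


def _uncertainty(work: TimeSeries, latent: LatentVector, options: FitOptions,
                 rss_val: float, t_scale: float, y_scale: float):
    """Standard errors in input units plus delta-method weight errors."""
    n, fix_yi = options.n, options.fix_yi
    theta_nat = _natural_vector(latent)
    fun = _natural_rss_fn(work.t, work.y, options.family, n, fix_yi)
    n_used = len(work)
    k = options.k
    if n_used <= k:
        return {}, None
    hess = hessian_fd(fun, theta_nat)
    bundle = covariance(hess, rss_val, n_used, k)
    names = _parameter_names(n, fix_yi)
    se_map = dict(zip(names, bundle.se))

    # scale back to input units
    scale = {"yi": y_scale, "yf": y_scale}
    for j in range(n):
        scale[f"lam{j + 1}"] = t_scale
        scale[f"rmax{j + 1}"] = y_scale / t_scale
    se = {nm: se_map[nm] * scale.get(nm, 1.0) for nm in names}

    # weight errors via the softmax Jacobian; gauge logit has zero variance
    zidx = [names.index(f"z{j + 1}") for j in range(n - 1)]
    cz = np.zeros((n, n))
    if zidx:
        sub = bundle.C[np.ix_(zidx, zidx)]
        cz[: n - 1, : n - 1] = sub
    se_p = delta_softmax(latent.z, cz)
    for j in range(n):
        se[f"p{j + 1}"] = float(se_p[j])
    se["_rank"] = bundle.rank
    se["_sigma2"] = bundle.sigma2 * y_scale**2
    return se, bundle.C


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def fit(data: TimeSeries, options: FitOptions) -> FitResult:
    """Run the complete robust fitting pipeline on one time series."""
    k = options.k
    if len(data) <= k:
        raise ValueError(
            f"insufficient data: N={len(data)} <= k={k} (stage: validate)"
        )
    work, t_scale, y_scale, reflect_c = _normalize(data, options)
    rng = np.random.default_rng(options.seed)

    logger.info("stage=heuristic_init n=%d family=%s", options.n, options.family)
    init = heuristic_init(work, options.n, options.fix_yi, options.de_popsize, rng)

    logger.info("stage=global_DE")
    latent, de_converged = fit_global(work, options, init=init)
    latent = fit_local(work, latent, options, loss="charbonnier")

    if options.run_outliers:
        logger.info("stage=ROUT q=%.4g", options.fdr_q)
        pred = _predict_free(
            latent.to_free(), work.t, options.family, options.n, options.fix_yi
        )
        resid = work.y - pred
        report = flag_outliers(resid, k=k, q=options.fdr_q)
    else:
        report = OutlierReport(
            mask=np.zeros(len(work), dtype=bool),
            q=options.fdr_q,
            rsdr=0.0,
            pvalues=np.ones(len(work)),
            excluded_indices=[],
        )
    keep = ~report.mask
    n_used = int(np.count_nonzero(keep))
    if n_used <= k:
        raise ValueError(
            f"insufficient degrees of freedom after outlier removal: "
            f"N_used={n_used} <= k={k} (stage: rout)"
        )
    cleaned = work.subset(keep)

    logger.info("stage=local_LBFGSB n_used=%d", n_used)
    latent = fit_local(cleaned, latent, options, loss="rss")

    pred_clean = _predict_free(
        latent.to_free(), cleaned.t, options.family, options.n, options.fix_yi
    )
    resid_clean = (cleaned.y - pred_clean) * y_scale  # input units
    rss_val = float(np.dot(resid_clean, resid_clean))
    loglik = objectives.profiled_loglik(resid_clean)
    tss = float(np.sum((cleaned.y * y_scale - np.mean(cleaned.y * y_scale)) ** 2))
    r2 = 1.0 - rss_val / tss if tss > 0 else math.nan

    from .selection import information_criterion  # late import avoids a cycle

    ic = {}
    for which in ("aic", "aicc", "bic"):
        try:
            ic[which] = information_criterion(loglik, k, n_used, which)
        except ValueError:
            ic[which] = math.nan

    logger.info("stage=uncertainty")
    rss_norm = rss_val / y_scale**2
    se, cov_mat = _uncertainty(cleaned, latent, options, rss_norm, t_scale, y_scale)

    model = _denormalize_model(decode(latent), t_scale, y_scale, reflect_c)
    provenance = {
        "options": options.to_dict(),
        "t_scale": t_scale,
        "y_scale": y_scale,
        "decreasing": reflect_c is not None,
    }
    return FitResult(
        model=model,
        theta_hat=latent,
        rss=rss_val,
        loglik=loglik,
        ic=ic,
        outliers=report,
        se=se,
        cov=cov_mat,
        n_used=n_used,
        converged=de_converged,
        provenance=provenance,
        r2=r2,
    )
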