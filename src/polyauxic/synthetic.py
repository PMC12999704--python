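"""Synthetic mono- and polyauxic datasets with known ground truth.

Data are the exact model mean (the generator calls the same evaluation code
as the fitter, never a duplicated formula) plus i.i.d. Gaussian measurement
noise, optionally contaminated with additive gross outliers and optionally
truncated before the plateau the way early-terminated batch assays are
(sampling stops once the per-step increment falls below a fraction of the
accumulated value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import (
    BOLTZMANN,
    GOMPERTZ,
    KineticModel,
    PhaseParams,
    TimeSeries,
    eval_polyauxic,
    inflection_time,
)

__all__ = [
    "SyntheticSpec",
    "default_grid",
    "simulate",
    "inject_outliers",
    "truncate_plateau",
    "benchmark_suite",
]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset; the seed fully determines it."""

    model: KineticModel
    t_grid: np.ndarray
    noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 10.0
    truncation_threshold: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if not (0.0 <= self.truncation_threshold < 1.0):
            raise ValueError("truncation_threshold must be in [0, 1)")


def default_grid(model: KineticModel, n_points: int = 60) -> np.ndarray:
    """Uniform grid covering all phases plus the final plateau.

    Spans [0, 1.2 * last inflection + 3 / r_min] so the slowest phase has
    time to saturate.
    """
    last_infl = max(
        inflection_time(model.family, model.yi, model.yf, ph.rmax, ph.lam)
        for ph in model.phases
    )
    r_min = min(ph.rmax for ph in model.phases)
    t_end = 1.2 * last_infl + 3.0 / r_min
    return np.linspace(0.0, t_end, n_points)


def simulate(spec: SyntheticSpec) -> tuple[TimeSeries, dict]:
    """Model mean plus Gaussian noise; returns the data and a truth record."""
    rng = np.random.default_rng(spec.seed)
    mean = eval_polyauxic(spec.model, spec.t_grid)
    y = mean + rng.normal(0.0, spec.noise_sd, size=spec.t_grid.size) if spec.noise_sd > 0 else mean.copy()
    ts = TimeSeries(spec.t_grid, y)
    truth = {
        "model": spec.model.to_dict(),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "outlier_indices": [],
    }
    if spec.outlier_fraction > 0:
        ts, flags = inject_outliers(
            ts,
            spec.outlier_fraction,
            spec.outlier_magnitude,
            seed=int(rng.integers(2**31)),
            noise_sd=spec.noise_sd,
        )
        truth["outlier_indices"] = [int(i) for i in np.nonzero(flags)[0]]
    if spec.truncation_threshold > 0:
        ts = truncate_plateau(ts, spec.truncation_threshold)
        truth["outlier_indices"] = [
            i for i in truth["outlier_indices"] if i < len(ts)
        ]
    return ts, truth


def inject_outliers(
    ts: TimeSeries,
    fraction: float,
    magnitude: float,
    seed: int | None = None,
    noise_sd: float = 1.0,
) -> tuple[TimeSeries, np.ndarray]:
    """Displace ceil(fraction*N) random points by +/- magnitude*noise_sd.

    Gross additive errors (rather than heavy-tailed noise) keep detection
    scoring unambiguous; the boolean flags mark the displaced points.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(ts)
    n_out = math.ceil(fraction * n)
    flags = np.zeros(n, dtype=bool)
    y = ts.y.copy()
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        y[idx] += signs * magnitude * noise_sd
        flags[idx] = True
    return TimeSeries(ts.t, y, ts.replicate, dict(ts.meta)), flags


def truncate_plateau(ts: TimeSeries, threshold: float) -> TimeSeries:
    """Drop the tail after the per-step increment falls below
    threshold * accumulated value.

    Emulates batch-assay termination rules that stop recording once the
    daily gain is a negligible fraction of the cumulative total, producing
    curves without a distinct stationary phase.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    if threshold == 0.0:
        return ts
    inc = np.diff(ts.y)
    acc = ts.y[1:]
    below = inc < threshold * np.abs(acc)
    # start scanning once growth is underway (after the steepest increment),
    # so lag-phase noise cannot trigger a spurious cut
    i0 = int(np.argmax(inc))
    cut = len(ts)
    hits = np.nonzero(below[i0:])[0]
    if hits.size:
        cut = i0 + int(hits[0]) + 1
    if cut < 5:
        raise ValueError(f"truncation would leave only {cut} points")
    mask = np.zeros(len(ts), dtype=bool)
    mask[:cut] = True
    return ts.subset(mask)


def _model(family, yi, yf, phases):
    return KineticModel(family, yi, yf, [PhaseParams(*ph) for ph in phases])


def benchmark_suite(seed: int = 0) -> dict[str, tuple[TimeSeries, dict]]:
    """Fixed catalogue of benchmark datasets with truth records.

    Covers monoauxic Boltzmann and Gompertz curves, diauxic variants with
    well-separated and overlapping phases, a three-phase curve with visually
    distinct plateaus, an outlier-contaminated dataset and a
    plateau-truncated one.  Noise is 1% of amplitude throughout, a typical
    relative precision for cumulative gas or biomass measurements.
    """
    rng = np.random.default_rng(seed)
    catalogue: dict[str, tuple[TimeSeries, dict]] = {}

    def add(name, model, **kw):
        sub = int(rng.integers(2**31))
        grid = kw.pop("t_grid", default_grid(model))
        spec = SyntheticSpec(model, grid, seed=sub, **kw)
        catalogue[name] = simulate(spec)

    mono_b = _model(BOLTZMANN, 0.0, 1.0, [(1.0, 5.0, 0.05)])
    mono_g = _model(GOMPERTZ, 0.0, 1.0, [(1.0, 5.0, 0.05)])
    di_sep = _model(GOMPERTZ, 0.0, 1.0, [(0.4, 5.0, 0.05), (0.6, 40.0, 0.02)])
    di_overlap = _model(GOMPERTZ, 0.0, 1.0, [(0.5, 5.0, 0.04), (0.5, 25.0, 0.03)])
    tri = _model(
        BOLTZMANN, 0.0, 1.0, [(0.3, 5.0, 0.08), (0.4, 40.0, 0.06), (0.3, 80.0, 0.05)]
    )

    add("mono_boltzmann", mono_b, noise_sd=0.01)
    add("mono_gompertz", mono_g, noise_sd=0.01)
    add("diauxic_separated", di_sep, noise_sd=0.01)
    add("diauxic_overlapping", di_overlap, noise_sd=0.01)
    add("triauxic_distinct", tri, noise_sd=0.01)
    add("diauxic_outliers", di_sep, noise_sd=0.01, outlier_fraction=0.05)
    add(
        "mono_gompertz_truncated",
        mono_g,
        noise_sd=0.01,
        truncation_threshold=0.01,
        t_grid=np.linspace(0.0, 60.0, 60),
    )
    return catalogue
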