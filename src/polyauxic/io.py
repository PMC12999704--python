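"""File I/O: CSV time series in, JSON/CSV reports out.

Input is a headed CSV with columns ``time,value[,replicate]``.  Reports are
written as (a) a JSON file carrying every fitted parameter with its standard
error, the fit statistics and a verbatim echo of the configuration, (b) a
curve CSV with observed, fitted and per-phase component columns plus the
outlier flag, and (c) a per-n selection CSV when a phase sweep was run.
All numbers are copied from the fit result; nothing is recomputed at
serialization time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import KineticModel, PhaseParams, TimeSeries, eval_polyauxic
from .optimize import FitResult
from .selection import SelectionResult

__all__ = ["read_timeseries", "write_report", "write_timeseries"]


def read_timeseries(path) -> TimeSeries:
    """Read and validate a ``time,value[,replicate]`` CSV, sorted by time."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("time", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric entry in column {col!r} at row {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise ValueError(f"{path}: empty cell in column {col!r} at row {row}")
        df[col] = coerced
    if len(df) < 3:
        raise ValueError(f"{path}: need at least 3 rows, found {len(df)}")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return TimeSeries(df["time"].to_numpy(), df["value"].to_numpy(), rep)


def write_timeseries(ts: TimeSeries, path) -> Path:
    path = Path(path)
    data = {"time": ts.t, "value": ts.y}
    if ts.replicate is not None:
        data["replicate"] = ts.replicate
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def _phase_components(model: KineticModel, t: np.ndarray) -> dict[str, np.ndarray]:
    """Cumulative contribution of each phase, sharing the model's yi."""
    out = {}
    for j, ph in enumerate(model.phases, start=1):
        sub = KineticModel(
            model.family,
            model.yi,
            model.yi + model.amplitude * ph.p,
            [PhaseParams(1.0, ph.lam, ph.rmax)],
        )
        out[f"phase_{j}"] = eval_polyauxic(sub, t)
    return out


def write_report(result, data: TimeSeries, outdir, stem: str = "fit") -> dict[str, Path]:
    """Write the JSON report plus curve/selection CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if isinstance(result, SelectionResult):
        sel_path = outdir / f"{stem}_selection.csv"
        pd.DataFrame(result.to_dict()["records"]).to_csv(sel_path, index=False)
        paths["selection"] = sel_path
        payload = result.to_dict()
        fit_result = result.best
    elif isinstance(result, FitResult):
        payload = result.to_dict()
        fit_result = result
    else:
        raise TypeError(f"cannot report a {type(result).__name__}")

    json_path = outdir / f"{stem}_report.json"
    json_path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    paths["report"] = json_path

    model = fit_result.model
    fitted = eval_polyauxic(model, data.t)
    outlier = np.zeros(len(data), dtype=int)
    # outlier indices refer to the (sorted) input order
    for i in fit_result.outliers.excluded_indices:
        outlier[i] = 1
    curve = {"time": data.t, "observed": data.y, "fitted": fitted}
    curve.update(_phase_components(model, data.t))
    curve["outlier"] = outlier
    curve_path = outdir / f"{stem}_curve.csv"
    pd.DataFrame(curve).to_csv(curve_path, index=False)
    paths["curve"] = curve_path
    return paths
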