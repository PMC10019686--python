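"""Tabular I/O: environment traces, gas-exchange datasets, curves.

CSV dialects
------------
Trace:    time_s, I_umol_m2_s, Tl_K, ca_umol_mol
Dataset:  trace columns plus gtc_m, ci_m, An_m
Curves:   kind, replicate, x, y, Tl_K, ca_umol_mol [, ci]

Short aliases (I, Tl, ca) are accepted for the trace columns, and a
``tl_in_celsius`` flag converts leaf temperature from °C on ingest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import SteadyStateCurve
from .estimate import GasExchangeDataset
from .simulate import EnvironmentTrace

logger = logging.getLogger(__name__)

_TRACE_ALIASES = {
    "time_s": ("time_s", "t", "time"),
    "I": ("I_umol_m2_s", "I", "irradiance"),
    "Tl": ("Tl_K", "Tl", "Tl_C", "leaf_temp"),
    "ca": ("ca_umol_mol", "ca"),
}
_MEASURED = ("gtc_m", "ci_m", "An_m")


def _pick(frame: pd.DataFrame, canonical: str) -> str:
    for name in _TRACE_ALIASES[canonical]:
        if name in frame.columns:
            return name
    raise ValueError(
        f"missing required column {canonical!r} "
        f"(accepted names: {', '.join(_TRACE_ALIASES[canonical])})"
    )


def _trace_from_frame(frame: pd.DataFrame, tl_in_celsius: bool,
                      label: str) -> tuple[EnvironmentTrace, pd.DataFrame]:
    cols = {c: _pick(frame, c) for c in _TRACE_ALIASES}
    n_raw = len(frame)
    frame = frame.dropna(subset=list(cols.values()))
    if len(frame) < n_raw:
        logger.info("dropped %d rows with missing values", n_raw - len(frame))
    t = frame[cols["time_s"]].to_numpy(dtype=float)
    if np.unique(t).size < t.size:
        raise ValueError("duplicated timestamps in input")
    Tl = frame[cols["Tl"]].to_numpy(dtype=float)
    if tl_in_celsius or cols["Tl"].endswith("_C"):
        Tl = Tl + 273.15
    trace = EnvironmentTrace(
        t=t, I=frame[cols["I"]].to_numpy(dtype=float), Tl=Tl,
        ca=frame[cols["ca"]].to_numpy(dtype=float), label=label,
    )
    return trace, frame


def read_trace(path: str | Path, *, tl_in_celsius: bool = False) -> EnvironmentTrace:
    """Read an environment trace CSV."""
    frame = pd.read_csv(path)
    trace, _ = _trace_from_frame(frame, tl_in_celsius, Path(path).stem)
    return trace


def write_trace(trace: EnvironmentTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def load_dataset(path: str | Path, *, tl_in_celsius: bool = False) -> GasExchangeDataset:
    """Read a gas-exchange dataset CSV (trace plus measured outputs)."""
    frame = pd.read_csv(path)
    for col in _MEASURED:
        if col not in frame.columns:
            raise ValueError(f"missing required measured column {col!r}")
    n_raw = len(frame)
    frame = frame.dropna(subset=list(_MEASURED))
    if len(frame) < n_raw:
        logger.info("dropped %d rows with missing measured values", n_raw - len(frame))
    trace, frame = _trace_from_frame(frame, tl_in_celsius, Path(path).stem)
    return GasExchangeDataset(
        trace=trace,
        gtc_m=frame["gtc_m"].to_numpy(dtype=float),
        ci_m=frame["ci_m"].to_numpy(dtype=float),
        An_m=frame["An_m"].to_numpy(dtype=float),
        metadata={"source": str(path)},
    )


def write_dataset(dataset: GasExchangeDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_curves(path: str | Path) -> list[SteadyStateCurve]:
    """Read steady-state curves (long format, one row per point)."""
    frame = pd.read_csv(path)
    required = {"kind", "replicate", "x", "y", "Tl_K", "ca_umol_mol"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing required curve columns: {sorted(missing)}")
    curves = []
    for (kind, rep), grp in frame.groupby(["kind", "replicate"], sort=True):
        ci = grp["ci"].to_numpy(dtype=float) if "ci" in grp.columns else None
        if ci is not None and np.any(~np.isfinite(ci)):
            ci = None
        curves.append(SteadyStateCurve(
            kind=str(kind), x=grp["x"].to_numpy(dtype=float),
            y=grp["y"].to_numpy(dtype=float), replicate=int(rep),
            Tl=float(grp["Tl_K"].iloc[0]), ca=float(grp["ca_umol_mol"].iloc[0]),
            ci=ci,
        ))
    return curves


def write_curves(curves: list[SteadyStateCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for i in range(c.x.size):
            row = {"kind": c.kind, "replicate": c.replicate, "x": c.x[i],
                   "y": c.y[i], "Tl_K": c.Tl, "ca_umol_mol": c.ca}
            if c.ci is not None:
                row["ci"] = c.ci[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
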