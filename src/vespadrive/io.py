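"""Serialisation of trajectories, scan results and run metadata.

Trajectories and scans are written as plain CSV ('.' decimal separator,
one row per generation or grid cell, deterministic column order) with a
JSON metadata sidecar carrying the parameters, seed and package version
needed to reproduce the run.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .analysis import ScanResult
from .model_core import Trajectory
from .stochastic import StochasticResult


def metadata_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.json")


def _write_metadata(path: str | Path, metadata: dict[str, Any] | None) -> None:
    if metadata is None:
        return
    record = {"vespadrive_version": __version__, **metadata}
    try:
        metadata_path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing metadata next to {path}: {exc}") from exc


def write_trajectory(
    trajectory: Trajectory,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
    fmt: str = "csv",
) -> None:
    """Write a per-generation trajectory table (CSV or JSON records)."""
    df = trajectory.to_dataframe()
    _write_table(df, path, fmt)
    _write_metadata(path, metadata)


def write_scan(
    scan: ScanResult,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
    fmt: str = "csv",
) -> None:
    """Write a long-format scan table, one row per grid cell."""
    _write_table(scan.data, path, fmt)
    _write_metadata(path, metadata)


def write_stochastic_summary(
    result: StochasticResult,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
    fmt: str = "csv",
) -> None:
    """Write the per-generation replicate summary of a stochastic run."""
    meta = dict(metadata or {})
    meta["extinction_probability"] = result.extinction_probability
    _write_table(result.summary(), path, fmt)
    _write_metadata(path, meta)


def _write_table(df: pd.DataFrame, path: str | Path, fmt: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "json":
            path.write_text(df.to_json(orient="records", indent=2))
        else:
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing table to {path}: {exc}") from exc


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read back a trajectory table written by :func:`write_trajectory`."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.read_json(path, orient="records")
    else:
        df = pd.read_csv(path)
    if "events" in df.columns:  # empty event tags come back as NaN
        df["events"] = df["events"].fillna("").astype(str)
    return df
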