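"""Result serialisation: HDF5 (exact) and CSV (formatted) time series,
JSON for measures and resolved configuration."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .params import ModelParameters, SCHEMA_VERSION, STATE_COLUMNS
from .engine import SimulationResult

__all__ = ["write_result", "read_result", "write_measures", "FormatError"]


class FormatError(IOError):
    """Schema mismatch or unreadable result file."""


def write_result(result: SimulationResult, path) -> None:
    """Write a simulation result; format chosen by suffix (.h5/.hdf5/.csv).

    HDF5 round-trips arrays exactly; CSV stores the time series at full
    repr precision plus a JSON sidecar with events and parameters.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["dt_ms"] = result.dt_ms
            f.attrs["columns"] = ",".join(result.columns)
            f.attrs["params_yaml"] = yaml.safe_dump(result.params.to_dict())
            f.create_dataset("t", data=result.t)
            f.create_dataset("y", data=result.y)
            f.create_dataset("event_times", data=result.event_times)
            f.create_dataset("event_amps", data=result.event_amps)
    elif path.suffix == ".csv":
        df = result.to_dataframe()
        df.to_csv(path, index=False, float_format="%.17g")
        side = {
            "schema_version": SCHEMA_VERSION,
            "dt_ms": result.dt_ms,
            "columns": list(result.columns),
            "event_times": result.event_times.tolist(),
            "event_amps": result.event_amps.tolist(),
            "params": result.params.to_dict(),
        }
        path.with_suffix(".json").write_text(json.dumps(side, indent=1))
    else:
        raise FormatError(f"unsupported result format {path.suffix!r}")


def read_result(path) -> SimulationResult:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ver = int(f.attrs.get("schema_version", -1))
            if ver != SCHEMA_VERSION:
                raise FormatError(f"result schema version {ver} != {SCHEMA_VERSION}")
            params = ModelParameters.from_dict(
                yaml.safe_load(f.attrs["params_yaml"]))
            cols = tuple(f.attrs["columns"].split(","))
            return SimulationResult(
                t=f["t"][()], y=f["y"][()],
                event_times=f["event_times"][()],
                event_amps=f["event_amps"][()],
                dt_ms=float(f.attrs["dt_ms"]), params=params, columns=cols)
    if path.suffix == ".csv":
        side_path = path.with_suffix(".json")
        if not side_path.exists():
            raise FormatError("missing JSON sidecar for CSV result")
        side = json.loads(side_path.read_text())
        if side.get("schema_version") != SCHEMA_VERSION:
            raise FormatError("result schema version mismatch")
        df = pd.read_csv(path)
        cols = side.get("columns", list(STATE_COLUMNS))
        return SimulationResult(
            t=df["time_s"].to_numpy(), y=df[cols].to_numpy(),
            event_times=np.asarray(side["event_times"], dtype=float),
            event_amps=np.asarray(side["event_amps"], dtype=float),
            dt_ms=float(side["dt_ms"]),
            params=ModelParameters.from_dict(side["params"]),
            columns=tuple(cols))
    raise FormatError(f"unsupported result format {path.suffix!r}")


def write_measures(dsi, path) -> None:
    """Write a DSIResult (or any measure dict) as JSON."""
    payload = dsi.to_dict() if hasattr(dsi, "to_dict") else dict(dsi)
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
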