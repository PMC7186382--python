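"""Serialization of simulation results, metrics tables, and run manifests.

Time series are written as flat CSV with a fixed, unit-annotated schema
(one row per output sample); metrics as flat JSON or CSV tables keyed by
(protocol, perturbation, controller variant).  Existing files are never
overwritten unless explicitly allowed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimResult, TorqueSimResult

__all__ = [
    "OverwriteError",
    "RunManifest",
    "write_timeseries",
    "read_timeseries",
    "write_torque_timeseries",
    "write_metrics_json",
    "write_metrics_csv",
    "metrics_table",
]

#: float format used in CSV output; round-trip exact at this precision
_FLOAT_FORMAT = "%.12g"


class OverwriteError(FileExistsError):
    """Refusing to overwrite an existing output without ``overwrite=True``."""


def _check_path(path, overwrite: bool) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise OverwriteError(
            f"{path} exists; pass overwrite=True (CLI: --overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


@dataclass
class RunManifest:
    """Provenance of one CLI invocation, stored next to its outputs."""

    command: str
    config_path: str
    output_dir: str
    seed: int
    variant: str = "open"            # open | closed
    delay: float | None = None       # s
    protocol: str | None = None      # static | dynamic | None
    extra: dict = field(default_factory=dict)

    def save(self, path, overwrite: bool = False) -> None:
        path = _check_path(path, overwrite)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

def _muscle_columns(stem: str, names: list[str]) -> list[str]:
    return [f"{stem}_{n}" for n in names]


def timeseries_frame(result: SimResult, muscle_names: list[str]) -> pd.DataFrame:
    """Flat data frame of one musculoskeletal run (fixed column schema).

    Units: time s; elbow angle rad, velocity rad/s; stimulations and
    activity dimensionless in [0, 1] (u_closed may be negative); muscle,
    contact, and constraint forces N; active torque N m.
    """
    m = len(muscle_names)
    if result.u_open.shape[1] != m:
        raise ValueError(
            f"result has {result.u_open.shape[1]} muscles, got "
            f"{m} names")
    data = {
        "time_s": result.t,
        "elbow_angle_rad": result.phi,
        "elbow_velocity_rad_per_s": result.omega,
    }
    for stem, arr in (("u_open", result.u_open),
                      ("u_closed", result.u_closed),
                      ("u_total", result.u_total),
                      ("activity", result.activity),
                      ("force_N", result.force),
                      ("contact_force_N", result.contact_first)):
        for j, col in enumerate(_muscle_columns(stem, muscle_names)):
            data[col] = arr[:, j]
    data["constraint_force_x_N"] = result.constraint_force[:, 0]
    data["constraint_force_y_N"] = result.constraint_force[:, 1]
    data["active_torque_Nm"] = result.active_torque
    return pd.DataFrame(data)


def write_timeseries(result: SimResult, path, muscle_names: list[str],
                     overwrite: bool = False) -> Path:
    """Write one run as CSV; round-trips exactly at the written precision."""
    path = _check_path(path, overwrite)
    frame = timeseries_frame(result, muscle_names)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_torque_timeseries(result: TorqueSimResult, path,
                            overwrite: bool = False) -> Path:
    path = _check_path(path, overwrite)
    frame = pd.DataFrame({
        "time_s": result.t,
        "elbow_angle_rad": result.phi,
        "elbow_velocity_rad_per_s": result.omega,
        "torque_Nm": result.torque,
    })
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


# --------------------------------------------------------------------------
# metrics tables
# --------------------------------------------------------------------------

def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Flat metrics table; rows are dicts keyed at least by
    (protocol, perturbation, variant)."""
    required = {"protocol", "perturbation", "variant"}
    for row in rows:
        missing = required - set(row)
        if missing:
            raise ValueError(f"metrics row missing keys {sorted(missing)}")
    return pd.DataFrame(rows)


def write_metrics_csv(rows: list[dict], path, overwrite: bool = False) -> Path:
    path = _check_path(path, overwrite)
    metrics_table(rows).to_csv(path, index=False,
                               float_format=_FLOAT_FORMAT)
    return path


def write_metrics_json(payload, path, overwrite: bool = False) -> Path:
    path = _check_path(path, overwrite)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o).__name__}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
    return path
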