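"""File formats and configuration for trial bundles.

All interchange files are plain CSV/JSON/YAML with unit-suffixed column
names (mm, degrees, seconds).  A trial bundle is a directory holding the
scenario config, the angle streams, the synthetic ground truth and a
provenance record sufficient to re-create the run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import AnchorAngles, DeviceGeometry, ModelParams
from .simulator import TrialResult

__all__ = [
    "DataError",
    "TrialBundle",
    "load_config",
    "geometry_from_config",
    "params_from_config",
    "write_bundle",
    "read_bundle",
    "FLOAT_FORMAT",
]

#: decimal places for CSV round-trips (documented precision)
FLOAT_FORMAT = "%.9g"

ANGLE_COLUMNS = ["time_s", "tape", "end", "roll_deg", "pitch_deg", "yaw_deg"]
TRUTH_COLUMNS = ["time_s", "x_mm", "y_mm", "z_mm", "roll_deg", "airborne", "foot_z_mm"]
MARKER_COLUMNS = ["frame", "time_s", "label", "x_mm", "y_mm", "z_mm"]


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a mapping")
    return cfg


def geometry_from_config(cfg: dict) -> DeviceGeometry:
    kwargs = {}
    for key, name in (
        ("span_l_mm", "span_L"),
        ("spring_length_mm", "spring_length"),
        ("sensor_section_end_mm", "sensor_section_end"),
        ("tape_width_mm", "tape_width"),
    ):
        if key in cfg:
            kwargs[name] = float(cfg[key])
    return DeviceGeometry(**kwargs)


def params_from_config(cfg: dict) -> ModelParams:
    kwargs = {}
    if "segment_ratio" in cfg:
        kwargs["segment_ratio"] = float(cfg["segment_ratio"])
    if "spring_coeff" in cfg and cfg["spring_coeff"] is not None:
        kwargs["spring_coeff"] = float(cfg["spring_coeff"])
    if "small_angle_deg" in cfg:
        kwargs["small_angle_threshold"] = float(cfg["small_angle_deg"])
    return ModelParams(**kwargs)


def _angles_to_csv_frame(angles: AnchorAngles, tape: str) -> pd.DataFrame:
    df = angles.to_frame()
    df.insert(1, "tape", tape)
    return df[ANGLE_COLUMNS]


def _angles_from_csv(path: Path, tape: str | None) -> AnchorAngles:
    df = pd.read_csv(path)
    missing = set(ANGLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if tape is not None:
        df = df[df["tape"] == tape]
    if df.empty:
        raise DataError(f"{path}: no rows for tape {tape!r}")
    return AnchorAngles.from_frame(df)


@dataclass
class TrialBundle:
    """In-memory view of a trial bundle directory."""

    scenario: dict
    angles_mocap: AnchorAngles
    angles_imu: AnchorAngles
    truth: pd.DataFrame | None
    markers: pd.DataFrame | None
    provenance: dict


def write_bundle(
    out_dir: str | Path,
    trial: TrialResult,
    scenario: dict,
    seed: int | None = None,
    tape: str = "left",
) -> Path:
    """Write a trial to disk as a plain-text bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "scenario.yaml", "w") as fh:
        yaml.safe_dump(scenario, fh, sort_keys=False)
    _angles_to_csv_frame(trial.angles_mocap, tape).to_csv(
        out / "angles_mocap.csv", index=False, float_format=FLOAT_FORMAT
    )
    _angles_to_csv_frame(trial.angles_imu, tape).to_csv(
        out / "angles_imu.csv", index=False, float_format=FLOAT_FORMAT
    )
    trial.truth[TRUTH_COLUMNS].to_csv(out / "truth.csv", index=False, float_format=FLOAT_FORMAT)
    if trial.markers is not None:
        markers = trial.markers.copy()
        frame_ids = {t: i for i, t in enumerate(np.unique(markers["time_s"]))}
        markers.insert(0, "frame", markers["time_s"].map(frame_ids))
        markers[MARKER_COLUMNS].to_csv(out / "markers.csv", index=False, float_format=FLOAT_FORMAT)
    provenance = {
        "tapekin_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "n_frames": int(len(trial.time)),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return out


def read_bundle(bundle_dir: str | Path, tape: str = "left") -> TrialBundle:
    bundle = Path(bundle_dir)
    if not bundle.is_dir():
        raise DataError(f"bundle directory {bundle} does not exist")
    scenario_path = bundle / "scenario.yaml"
    scenario = load_config(scenario_path) if scenario_path.exists() else {}
    truth_path = bundle / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    markers_path = bundle / "markers.csv"
    markers = pd.read_csv(markers_path) if markers_path.exists() else None
    prov_path = bundle / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return TrialBundle(
        scenario=scenario,
        angles_mocap=_angles_from_csv(bundle / "angles_mocap.csv", tape),
        angles_imu=_angles_from_csv(bundle / "angles_imu.csv", tape),
        truth=truth,
        markers=markers,
        provenance=provenance,
    )
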