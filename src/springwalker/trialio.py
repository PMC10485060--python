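"""Reading and writing trial directories and tabular/JSON reports.

A trial directory holds one treadmill recording:

```
trial_dir/
    meta.yaml          # schema_version, subject metadata, sampling rates
    kinematics.tsv     # time + marker/CoM/hip channels at the kinematic rate
    grf.tsv            # time + force-plate channels at the force rate
    ground_truth.json  # optional sidecar written by the synthetic generator
```

``kinematics.tsv`` columns: ``time, heel_x_L, heel_x_R, toe_x_L, toe_x_R,
com_x, com_y, hip_angle_L, hip_angle_R, hip_torque_L, hip_torque_R`` (metres,
radians with extension positive, N·m with flexion positive).
``grf.tsv`` columns: ``time, grf_x_L, grf_y_L, grf_x_R, grf_y_R`` (newtons,
anterior and vertical components, one force plate per side).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .pipeline import SIDES, MocapTrial

__all__ = ["write_trial", "read_trial", "read_ground_truth", "write_json"]

SCHEMA_VERSION = "1.0"

_KIN_COLUMNS = [
    "time",
    "heel_x_L", "heel_x_R", "toe_x_L", "toe_x_R",
    "com_x", "com_y",
    "hip_angle_L", "hip_angle_R", "hip_torque_L", "hip_torque_R",
]
_GRF_COLUMNS = ["time", "grf_x_L", "grf_y_L", "grf_x_R", "grf_y_R"]


class _CompactJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=1, cls=_CompactJSONEncoder) + "\n"
    )


def write_trial(trial_dir, trial: MocapTrial, ground_truth: dict | None = None) -> Path:
    """Write a trial to a directory in the documented layout."""
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": trial.subject_id,
        "subject_mass": float(trial.subject_mass),
        "belt_speed_nominal": float(trial.belt_speed_nominal),
        "belt_scale": float(trial.belt_scale),
        "kinematic_rate": float(trial.kinematic_rate),
        "grf_rate": float(trial.grf_rate),
    }
    (trial_dir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    kin = pd.DataFrame({
        "time": trial.kinematic_times,
        "heel_x_L": trial.heel_x["L"], "heel_x_R": trial.heel_x["R"],
        "toe_x_L": trial.toe_x["L"], "toe_x_R": trial.toe_x["R"],
        "com_x": trial.com_x, "com_y": trial.com_y,
        "hip_angle_L": trial.hip_angle["L"], "hip_angle_R": trial.hip_angle["R"],
        "hip_torque_L": trial.hip_torque["L"], "hip_torque_R": trial.hip_torque["R"],
    })
    kin.to_csv(trial_dir / "kinematics.tsv", sep="\t", index=False,
               float_format="%.6f")
    grf = pd.DataFrame({
        "time": trial.grf_times,
        "grf_x_L": trial.grf_x["L"], "grf_y_L": trial.grf_y["L"],
        "grf_x_R": trial.grf_x["R"], "grf_y_R": trial.grf_y["R"],
    })
    grf.to_csv(trial_dir / "grf.tsv", sep="\t", index=False, float_format="%.4f")
    if ground_truth is not None:
        write_json(trial_dir / "ground_truth.json", ground_truth)
    return trial_dir


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_trial(trial_dir) -> MocapTrial:
    """Read a trial directory; raises :class:`SchemaError` on layout problems."""
    trial_dir = Path(trial_dir)
    meta_path = trial_dir / "meta.yaml"
    kin_path = trial_dir / "kinematics.tsv"
    grf_path = trial_dir / "grf.tsv"
    missing = [p.name for p in (meta_path, kin_path, grf_path) if not p.exists()]
    if missing:
        raise SchemaError(
            f"{trial_dir}: not a trial directory, missing {missing} "
            f"(required: meta.yaml, kinematics.tsv, grf.tsv)"
        )
    meta = yaml.safe_load(meta_path.read_text())
    version = str(meta.get("schema_version", ""))
    if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(
            f"{meta_path}: unsupported schema_version {version!r} "
            f"(reader supports major version {SCHEMA_VERSION.split('.')[0]})"
        )
    for key in ("subject_mass", "belt_speed_nominal", "kinematic_rate", "grf_rate"):
        if key not in meta:
            raise SchemaError(f"{meta_path}: missing metadata key {key!r}")
    kin = pd.read_csv(kin_path, sep="\t")
    _require_columns(kin, _KIN_COLUMNS, kin_path)
    grf = pd.read_csv(grf_path, sep="\t")
    _require_columns(grf, _GRF_COLUMNS, grf_path)
    col = lambda df, name: df[name].to_numpy(dtype=float)
    return MocapTrial(
        kinematic_rate=float(meta["kinematic_rate"]),
        grf_rate=float(meta["grf_rate"]),
        heel_x={s: col(kin, f"heel_x_{s}") for s in SIDES},
        toe_x={s: col(kin, f"toe_x_{s}") for s in SIDES},
        com_x=col(kin, "com_x"),
        com_y=col(kin, "com_y"),
        hip_angle={s: col(kin, f"hip_angle_{s}") for s in SIDES},
        hip_torque={s: col(kin, f"hip_torque_{s}") for s in SIDES},
        grf_x={s: col(grf, f"grf_x_{s}") for s in SIDES},
        grf_y={s: col(grf, f"grf_y_{s}") for s in SIDES},
        subject_mass=float(meta["subject_mass"]),
        belt_speed_nominal=float(meta["belt_speed_nominal"]),
        belt_scale=float(meta.get("belt_scale", 1.0)),
        subject_id=str(meta.get("subject_id", "S00")),
    )


def read_ground_truth(trial_dir) -> dict | None:
    path = Path(trial_dir) / "ground_truth.json"
    if not path.exists():
        return None
    return json.loads(path.read_text())
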