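"""CSV/JSON interchange for strides, ground truth and trajectory estimates.

Formats (comma-separated, header row, '.' decimal):

* stride CSV: ``time_s, gx, gy, gz, ax, ay, az`` — gyro in rad/s, accel in g;
* events CSV: ``stride_id, file, i_ms_start, i_ms_end``;
* ground-truth CSV: ``time_s, sx, sy, sz, vx, vy, vz, qw, qx, qy, qz``;
* trajectory CSV: ``time_s, vx, vy, vz, sx, sy, sz`` plus a JSON sidecar with
  scalar summaries and run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .orientation import OrientationTrack
from .simulate import GroundTruth
from .stride import StrideRecording
from .trajectory import TrajectoryEstimate

__all__ = [
    "read_stride_csv",
    "write_stride_csv",
    "read_events_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_trajectory_csv",
    "write_dataset",
    "read_dataset",
]

STRIDE_COLUMNS = ["time_s", "gx", "gy", "gz", "ax", "ay", "az"]
TRUTH_COLUMNS = ["time_s", "sx", "sy", "sz", "vx", "vy", "vz", "qw", "qx", "qy", "qz"]


def read_stride_csv(
    path, i_ms_start: int = 0, i_ms_end: int = -1, delta_t: float | None = None
) -> StrideRecording:
    df = pd.read_csv(path)
    missing = [c for c in STRIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stride CSV {path} lacks columns: {missing}")
    t = df["time_s"].to_numpy()
    if delta_t is None:
        delta_t = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return StrideRecording(
        t,
        df[["gx", "gy", "gz"]].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(),
        delta_t=delta_t,
        i_ms_start=i_ms_start,
        i_ms_end=i_ms_end,
    )


def write_stride_csv(path, stride: StrideRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([stride.timestamps, stride.gyro, stride.accel]),
        columns=STRIDE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("stride_id", "i_ms_start", "i_ms_end"):
        if c not in df.columns:
            raise ValueError(f"events CSV {path} lacks column {c!r}")
    return df


def write_truth_csv(path, truth: GroundTruth) -> None:
    df = pd.DataFrame(
        np.column_stack(
            [
                truth.timestamps,
                truth.position,
                truth.velocity,
                truth.orientation.quaternions,
            ]
        ),
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_truth_csv(path) -> GroundTruth:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    pos = df[["sx", "sy", "sz"]].to_numpy()
    vel = df[["vx", "vy", "vz"]].to_numpy()
    quats = df[["qw", "qx", "qy", "qz"]].to_numpy()
    return GroundTruth(
        t, pos, vel, np.full_like(pos, np.nan), OrientationTrack(quats)
    )


def write_trajectory_csv(path, stride: StrideRecording, traj: TrajectoryEstimate,
                         metadata: dict | None = None) -> None:
    """Trajectory CSV plus a ``.json`` sidecar with summaries and metadata."""
    path = Path(path)
    t = stride.segment(stride.timestamps)
    df = pd.DataFrame(
        np.column_stack([t, traj.velocity, traj.position]),
        columns=["time_s", "vx", "vy", "vz", "sx", "sy", "sz"],
    )
    df.to_csv(path, index=False)
    summary = {
        "stride_length_m": traj.stride_length,
        "max_clearance_m": traj.max_clearance,
        **(metadata or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def write_dataset(out_dir, dataset) -> None:
    """Write a simulated dataset as stride/truth CSVs plus events and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = []
    meta = []
    for i, (spec, rec, truth) in enumerate(dataset):
        name = f"stride_{i:04d}"
        write_stride_csv(out / f"{name}.csv", rec)
        write_truth_csv(out / f"{name}_truth.csv", truth)
        events.append(
            {
                "stride_id": i,
                "file": f"{name}.csv",
                "i_ms_start": rec.i_ms_start,
                "i_ms_end": rec.i_ms_end,
            }
        )
        meta.append({"stride_id": i, **spec.__dict__})
    pd.DataFrame(events).to_csv(out / "events.csv", index=False)
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=list))


def read_dataset(in_dir) -> list[tuple[StrideRecording, GroundTruth | None]]:
    """Read back a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    events = read_events_csv(in_dir / "events.csv")
    out = []
    for _, row in events.iterrows():
        rec = read_stride_csv(
            in_dir / row["file"],
            i_ms_start=int(row["i_ms_start"]),
            i_ms_end=int(row["i_ms_end"]),
        )
        truth_path = in_dir / row["file"].replace(".csv", "_truth.csv")
        truth = read_truth_csv(truth_path) if truth_path.exists() else None
        out.append((rec, truth))
    return out
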