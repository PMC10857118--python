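"""File I/O: IMU CSV, event tables, parameter tables, config, manifests.

All on-disk formats are plain text (CSV / YAML / JSON).  The IMU reader
converts declared source units to the internal m/s² and rad/s convention
and applies the left-side pitch sign flip, so everything downstream sees
one canonical representation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .event_detection import EVENT_KINDS, DetectionConfig, GaitCycle, GaitEvent
from .evaluation import GroundTruth
from .signal_model import ImuRecording

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "write_events_csv",
    "read_events_csv",
    "write_reference_csv",
    "read_reference_csv",
    "load_config",
    "save_config",
    "build_manifest",
]

GRAVITY = 9.80665  # m/s² per g
DEG2RAD = np.pi / 180.0

IMU_COLUMNS = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

#: max deviation of a timestamp step from the nominal period
TIME_JITTER_FRACTION = 0.10


def read_imu_csv(path: str | Path, config: DetectionConfig) -> ImuRecording:
    """Load a six-axis IMU CSV into the internal representation.

    Expected header: ``t,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z`` with
    ``t`` in seconds; the ``t`` column may be omitted, in which case the
    configured sample rate defines an implicit uniform time base.  Units
    are converted per ``config.acc_units`` / ``config.gyro_units``, and
    for ``config.side == "left"`` the pitch rate is negated so the same
    detector applies to both legs.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path.name}: file contains no samples")

    bad = df[list(IMU_COLUMNS)].isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path.name}: non-finite value in data row {row}")

    fs = float(config.sample_rate_hz)
    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
        if np.isnan(t).any():
            row = int(np.flatnonzero(np.isnan(t))[0])
            raise ValueError(f"{path.name}: non-finite time in data row {row}")
        dt = np.diff(t)
        if dt.size:
            period = float(np.median(dt))
            if period <= 0:
                raise ValueError(f"{path.name}: non-increasing time column")
            off = np.abs(dt - period) > TIME_JITTER_FRACTION * period
            if off.any():
                row = int(np.flatnonzero(off)[0]) + 1
                raise ValueError(
                    f"{path.name}: non-uniform time step at data row {row}"
                )
            fs = 1.0 / period

    acc_scale = {"m_s2": 1.0, "g": GRAVITY}.get(config.acc_units)
    gyro_scale = {"rad_s": 1.0, "deg_s": DEG2RAD}.get(config.gyro_units)
    if acc_scale is None:
        raise ValueError(f"unknown acc_units {config.acc_units!r}")
    if gyro_scale is None:
        raise ValueError(f"unknown gyro_units {config.gyro_units!r}")

    gyro_y = df["gyro_y"].to_numpy(dtype=float) * gyro_scale
    if config.side == "left":
        gyro_y = -gyro_y  # canonical: positive pitch = thigh flexion

    return ImuRecording(
        sample_rate=fs,
        acc_ap=df["acc_x"].to_numpy(dtype=float) * acc_scale,
        acc_ml=df["acc_y"].to_numpy(dtype=float) * acc_scale,
        acc_v=df["acc_z"].to_numpy(dtype=float) * acc_scale,
        gyro_roll=df["gyro_x"].to_numpy(dtype=float) * gyro_scale,
        gyro_pitch=gyro_y,
        gyro_yaw=df["gyro_z"].to_numpy(dtype=float) * gyro_scale,
        side=config.side,
        units_declared={"acc": config.acc_units, "gyro": config.gyro_units},
    )


def write_imu_csv(path: str | Path, recording: ImuRecording) -> None:
    """Write a recording in internal units with an explicit time column."""
    df = pd.DataFrame(
        {
            "t": recording.times,
            "acc_x": recording.acc_ap,
            "acc_y": recording.acc_ml,
            "acc_z": recording.acc_v,
            "gyro_x": recording.gyro_roll,
            "gyro_y": recording.gyro_pitch,
            "gyro_z": recording.gyro_yaw,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# event tables

def write_events_csv(path: str | Path, cycles: list[GaitCycle]) -> None:
    """Detected events, one row per event: cycle_index,event,sample_index,time_s,valid,edge.

    The closing IC of each cycle is stored as ``NEXT_IC`` so the cycle
    structure round-trips losslessly.
    """
    rows = []
    for i, c in enumerate(cycles):
        named = [("IC", c.ic), ("OTO", c.oto), ("OIC", c.oic), ("TO", c.to),
                 ("NEXT_IC", c.next_ic)]
        for label, ev in named:
            if ev is None:
                continue
            rows.append(
                {
                    "cycle_index": i,
                    "event": label,
                    "sample_index": ev.sample_index,
                    "time_s": ev.time,
                    "valid": c.valid,
                    "edge": c.edge,
                }
            )
    pd.DataFrame(
        rows, columns=["cycle_index", "event", "sample_index", "time_s", "valid", "edge"]
    ).to_csv(path, index=False, float_format="%.9g")


def read_events_csv(path: str | Path) -> list[GaitCycle]:
    """Rebuild cycles from an events CSV; validity is re-derived from ordering."""
    df = pd.read_csv(path)
    required = {"cycle_index", "event", "sample_index", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{Path(path).name}: events CSV missing {sorted(required - set(df.columns))}")
    cycles: list[GaitCycle] = []
    for _, group in df.groupby("cycle_index", sort=True):
        ev: dict[str, GaitEvent] = {}
        for _, row in group.iterrows():
            label = str(row["event"])
            kind = "IC" if label == "NEXT_IC" else label
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event label {label!r}")
            ev[label] = GaitEvent(kind, int(row["sample_index"]), float(row["time_s"]))
        cyc = GaitCycle(
            ic=ev.get("IC"),
            oto=ev.get("OTO"),
            oic=ev.get("OIC"),
            to=ev.get("TO"),
            next_ic=ev.get("NEXT_IC"),
            edge=bool(group["edge"].iloc[0]) if "edge" in group else False,
        )
        times = [e.time if e else None for e in (cyc.ic, cyc.oto, cyc.oic, cyc.to, cyc.next_ic)]
        cyc.valid = None not in times and all(a < b for a, b in zip(times, times[1:]))
        cycles.append(cyc)
    return cycles


def write_reference_csv(path: str | Path, truth: GroundTruth) -> None:
    """Reference event table: ``event,time_s`` rows, ascending per kind."""
    rows = [
        {"event": kind, "time_s": float(t)}
        for kind in EVENT_KINDS
        for t in truth.events.get(kind, ())
    ]
    pd.DataFrame(rows, columns=["event", "time_s"]).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_reference_csv(path: str | Path, source: str = "force_plate") -> GroundTruth:
    df = pd.read_csv(path)
    if not {"event", "time_s"}.issubset(df.columns):
        raise ValueError(f"{Path(path).name}: reference CSV needs event,time_s columns")
    events = {
        kind: np.sort(df.loc[df["event"] == kind, "time_s"].to_numpy(dtype=float))
        for kind in EVENT_KINDS
    }
    return GroundTruth(events=events, source=source)


# ---------------------------------------------------------------------------
# configuration and manifests

def save_config(path: str | Path, config: DetectionConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> DetectionConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(DetectionConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DetectionConfig(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    config: DetectionConfig | None = None,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
    counts: dict[str, int] | None = None,
) -> dict:
    """Provenance record for one CLI run."""
    config_hash = None
    if config is not None:
        blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
        config_hash = hashlib.sha256(blob).hexdigest()
    return {
        "tool": "thighgait",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_sha256": config_hash,
        "inputs": {str(p): _sha256(p) for p in (inputs or [])},
        "counts": counts or {},
    }


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
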