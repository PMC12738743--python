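"""File formats and run configuration.

On-disk dialects:

* IMU recordings: CSV with a mandatory header row and columns
  ``t_s, acc_x_g, acc_y_g, acc_z_g, gyr_x_dps, gyr_y_dps, gyr_z_dps,
  q_w, q_x, q_y, q_z``. Metadata (fs, task, placement, side) travels in
  ``#``-prefixed comment lines above the header.
* LFP sessions: JSON with keys ``beta_peak_hz, band_low_hz, band_high_hz,
  band_power`` (array of ``{t_s, power}``), optional ``raw``
  (``{fs_hz, samples}``) and ``segments`` (array of
  ``{label, t_start_s, t_end_s}``). Extra keys are tolerated.
* Protocols and run configs: YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .imu import ImuRecording
from .lfp import LfpSession
from .protocol import SessionProtocol

__all__ = [
    "IMU_COLUMNS",
    "RunConfig",
    "write_imu_csv",
    "read_imu_csv",
    "write_lfp_json",
    "read_lfp_json",
    "write_protocol",
    "read_protocol",
    "load_config",
    "config_hash",
]

IMU_COLUMNS = [
    "t_s",
    "acc_x_g", "acc_y_g", "acc_z_g",
    "gyr_x_dps", "gyr_y_dps", "gyr_z_dps",
    "q_w", "q_x", "q_y", "q_z",
]

PathLike = Union[str, Path]


def write_imu_csv(rec: ImuRecording, path: PathLike) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.accel, rec.gyro, rec.quat]),
        columns=IMU_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs} task={rec.task} placement={rec.placement} "
                 f"side={rec.side}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_imu_csv(path: PathLike) -> ImuRecording:
    meta = {"fs": None, "task": "FS", "placement": "ankle", "side": "right"}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    df = pd.read_csv(path, comment="#")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[IMU_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 3).tolist()  # 1-based + meta + header
        raise ValueError(f"{path}: malformed rows at lines {lines[:5]}")
    t = df["t_s"].to_numpy(float)
    fs = float(meta["fs"]) if meta["fs"] else 1.0 / float(np.median(np.diff(t)))
    return ImuRecording(
        t=t,
        accel=df[IMU_COLUMNS[1:4]].to_numpy(float),
        gyro=df[IMU_COLUMNS[4:7]].to_numpy(float),
        quat=df[IMU_COLUMNS[7:11]].to_numpy(float),
        fs=fs,
        placement=str(meta["placement"]),
        task=str(meta["task"]),
        side=str(meta["side"]),
    )


def write_lfp_json(session: LfpSession, path: PathLike) -> None:
    low, high = session.band
    doc = {
        "beta_peak_hz": session.beta_peak_hz,
        "band_low_hz": low,
        "band_high_hz": high,
        "band_power": [
            {"t_s": float(t), "power": float(p)}
            for t, p in zip(session.band_power_t, session.band_power)
        ],
        "segments": [
            {"label": lab, "t_start_s": t0, "t_end_s": t1}
            for lab, t0, t1 in session.segments
        ],
    }
    if session.raw is not None:
        doc["raw"] = {"fs_hz": session.fs_raw,
                      "samples": [float(x) for x in session.raw]}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_lfp_json(path: PathLike) -> LfpSession:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("beta_peak_hz", "band_power", "segments"):
        if key not in doc:
            raise ValueError(f"{path}: missing key {key!r}")
    bp = doc["band_power"]
    raw = doc.get("raw")
    return LfpSession(
        beta_peak_hz=float(doc["beta_peak_hz"]),
        band_power_t=np.array([s["t_s"] for s in bp], dtype=float),
        band_power=np.array([s["power"] for s in bp], dtype=float),
        segments=tuple(
            (s["label"], float(s["t_start_s"]), float(s["t_end_s"]))
            for s in doc["segments"]
        ),
        raw=None if raw is None else np.asarray(raw["samples"], dtype=float),
        fs_raw=None if raw is None else float(raw["fs_hz"]),
    )


def write_protocol(protocol: SessionProtocol, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol.to_dict(), fh, sort_keys=False)


def read_protocol(path: PathLike) -> SessionProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SessionProtocol.from_dict(doc)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for an end-to-end run."""

    seed: int = 0
    n_participants: int = 10
    n_non_responders: int = 2
    responder_factor: float = 0.85
    non_responder_factor: float = 1.10
    # synthetic movement parameters
    fs_rate_hz: float = 1.5
    fs_base_height: float = 0.12
    hps_rate_hz: float = 1.5
    hps_amplitude_deg: float = 160.0
    noise_sd: float = 0.1
    post_effect_gain: float = 0.6   # couples beta reduction to motor gains
    # preprocessing / kinematics
    highpass_cutoff_hz: float = 0.5
    target_fs_hz: float = 50.0
    peaks_min_distance_s: float = 0.25
    segmentation_mode: str = "manual"
    # statistics
    bootstrap_B: int = 2000
    tost_sesoi_factor: float = 0.3
    # LFP generation
    lfp_fs_raw: float = 250.0
    lfp_background_exponent: float = 1.0

    def metric_config(self) -> dict:
        return {
            "highpass_cutoff_hz": self.highpass_cutoff_hz,
            "target_fs_hz": self.target_fs_hz,
            "peaks_min_distance_s": self.peaks_min_distance_s,
        }


def load_config(path: Optional[PathLike] = None, **overrides) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    doc.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**doc)


def config_hash(config: RunConfig) -> str:
    """Stable hash uniquely identifying a resolved configuration."""
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
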