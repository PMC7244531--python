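"""CSV/YAML plumbing for track tables, events, measurements and reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registration import SimilarityTransform
from .synthetic import TRACK_COLUMNS

__all__ = [
    "read_tracks",
    "write_tracks",
    "write_transform",
    "read_transform",
    "write_drift",
    "read_drift",
    "write_events",
    "write_helix_measurements",
    "write_report",
]

_NUMERIC = ["frame", "time_s", "x_nm", "y_nm"]


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRACK_COLUMNS if c in tracks.columns]
    extra = [c for c in tracks.columns if c not in cols]
    tracks[cols + extra].to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track-table CSV; corrupt rows raise with the offending line number."""
    tracks = pd.read_csv(path)
    missing = [c for c in ("frame", "time_s", "channel", "object_id", "role", "x_nm", "y_nm") if c not in tracks.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in _NUMERIC:
        converted = pd.to_numeric(tracks[col], errors="coerce")
        bad = converted.isna() & tracks[col].notna() | tracks[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: corrupt value in column {col!r} at line {line}")
        tracks[col] = converted
    tracks["frame"] = tracks["frame"].astype(int)
    return tracks


def write_transform(
    transform: SimilarityTransform, residual_rms_nm: float, path: str | Path
) -> None:
    payload = {
        "rotation_deg": float(np.degrees(transform.rotation)),
        "scale": float(transform.scale),
        "tx_nm": float(transform.translation[0]),
        "ty_nm": float(transform.translation[1]),
        "residual_rms_nm": float(residual_rms_nm),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_transform(path: str | Path) -> tuple[SimilarityTransform, float]:
    payload = yaml.safe_load(Path(path).read_text())
    tform = SimilarityTransform(
        rotation=float(np.radians(payload["rotation_deg"])),
        scale=float(payload["scale"]),
        translation=(float(payload["tx_nm"]), float(payload["ty_nm"])),
    )
    return tform, float(payload.get("residual_rms_nm", float("nan")))


def write_drift(drift: pd.DataFrame, path: str | Path) -> None:
    drift.to_csv(path, index=False)


def read_drift(path: str | Path) -> pd.DataFrame:
    drift = pd.read_csv(path)
    drift["frame"] = drift["frame"].astype(int)
    return drift


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    cols = ["event_id", "frame", "time_s", "s_nm", "x_nm", "region", "polarity"]
    events[[c for c in cols if c in events.columns]].to_csv(path, index=False)


def write_helix_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    measurements.to_csv(path, index=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(report), sort_keys=False))
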