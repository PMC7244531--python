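"""Synthetic track tables for microtubule-microtubule sliding assays.

The generator emulates the tracked output of a dual-color sliding assay in
which short "transport" microtubules are propelled along a long, straight,
suspended "template" microtubule by cross-linking motors.  The transport
microtubule advances at constant speed and winds around the template on a
helical path of radius

    R = (template_diameter + transport_diameter) / 2 + motor_extension,

which is 43 nm at the defaults (25 nm microtubules, 18 nm motor extension).
Only the 2D image projection is emitted: the sideways coordinate is
``R * sin(phi)`` plus isotropic Gaussian localization noise.  Where the
transport microtubule overlaps a surface-immobilized ridge its azimuth is
clamped to the right-hand side (sideways distance -R for right-handed
motion), mirroring the ridge-locking observed in the assay.  Fiducial beads
carry linear stage drift, and far-red coordinates are additionally passed
through a configurable inter-channel similarity distortion.

Sign convention: positive sideways distance lies to the LEFT of the motion
direction (+90 degrees counterclockwise in the image plane).  Right-handed
helical motion corresponds to the azimuthal phase decreasing with forward
motion, so the ridge-locked side is the right-hand side (sideways = -R).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .registration import SimilarityTransform

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "TRACK_COLUMNS",
    "generate_helical_event",
    "generate_parallel_event",
    "generate_speckle_trace",
    "generate_cohort",
]

TRACK_COLUMNS = [
    "frame",
    "time_s",
    "channel",
    "object_id",
    "role",
    "x_nm",
    "y_nm",
    "intensity",
    "vertex",
]

#: azimuthal phase advance per unit of forward motion, by handedness
_PHASE_SIGN = {"right": -1.0, "left": +1.0}


@dataclasses.dataclass
class SceneConfig:
    """Parameters of one synthetic sliding event.

    Lengths in nm, times in s.  Defaults reproduce the canonical assay
    geometry: 25 nm microtubules, 18 nm motor extension (helical radius
    43 nm), and a sliding speed of 100 nm/s sampled at 5 frames/s.
    """

    template_diameter: float = 25.0
    transport_diameter: float = 25.0
    motor_extension: float = 18.0
    helical_pitch: float = 1300.0
    handedness: str = "right"
    sliding_velocity: float = 100.0
    frame_interval: float = 0.2
    n_frames: int = 400
    localization_sd: float = 10.0
    ridge_intervals: tuple[tuple[float, float], ...] = ()
    bead_positions: tuple[tuple[float, float], ...] = (
        (2000.0, 4000.0),
        (15000.0, 1500.0),
        (8000.0, -5000.0),
    )
    drift_rate: tuple[float, float] = (0.0, 0.0)
    channel_transform: SimilarityTransform = dataclasses.field(
        default_factory=SimilarityTransform.identity
    )
    initial_phase: float = 0.0
    rng_seed: int = 0
    template_length: float = 20000.0
    transport_length: float = 1800.0
    start_position: float = 500.0
    template_vertex_spacing: float = 500.0
    template_frames: int = 60
    intensity_baseline: float = 1000.0
    modulation_depth: float = 0.5
    intensity_noise_sd: float = 0.0

    @property
    def helical_radius(self) -> float:
        return (self.template_diameter + self.transport_diameter) / 2.0 + self.motor_extension

    @property
    def helical_diameter(self) -> float:
        return 2.0 * self.helical_radius

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def validate(self) -> None:
        for name in (
            "template_diameter",
            "transport_diameter",
            "motor_extension",
            "helical_pitch",
            "sliding_velocity",
            "frame_interval",
            "template_length",
            "transport_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.handedness not in _PHASE_SIGN:
            raise ValueError(f"handedness must be 'right' or 'left', got {self.handedness!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be >= 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        for lo, hi in self.ridge_intervals:
            if not (0.0 <= lo < hi <= self.template_length):
                raise ValueError(
                    f"ridge interval [{lo}, {hi}) outside template span "
                    f"[0, {self.template_length})"
                )


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters of one event, for recovery tests.

    ``true_channel_transform`` is the CORRECTION transform (far-red -> red),
    i.e. the inverse of the distortion the generator applied.
    """

    event_id: str
    true_pitch: float
    true_diameter: float
    true_velocity: float
    true_handedness: str
    true_period_s: float
    true_channel_transform: SimilarityTransform
    true_drift_rate: tuple[float, float]
    true_azimuth: float = float("nan")


def _footprint_on_ridge(
    s: np.ndarray, half_length: float, ridges: Sequence[tuple[float, float]]
) -> np.ndarray:
    """True where the transport footprint [s - L/2, s + L/2) overlaps any ridge."""
    mask = np.zeros_like(s, dtype=bool)
    for lo, hi in ridges:
        mask |= (s + half_length > lo) & (s - half_length < hi)
    return mask


def _template_rows(
    config: SceneConfig, rng: np.random.Generator, drift: np.ndarray
) -> list[pd.DataFrame]:
    nv = int(np.floor(config.template_length / config.template_vertex_spacing)) + 1
    vx = np.linspace(0.0, config.template_length, nv)
    vy = np.zeros(nv)
    n_tf = min(config.n_frames, config.template_frames)
    rows = []
    for k in range(n_tf):
        noise = rng.normal(0.0, config.localization_sd, size=(nv, 2))
        rows.append(
            pd.DataFrame(
                {
                    "frame": k,
                    "time_s": k * config.frame_interval,
                    "channel": "red",
                    "object_id": "template0",
                    "role": "template",
                    "x_nm": vx + drift[k, 0] + noise[:, 0],
                    "y_nm": vy + drift[k, 1] + noise[:, 1],
                    "intensity": np.nan,
                    "vertex": np.arange(nv),
                }
            )
        )
    return rows


def _bead_rows(
    config: SceneConfig, rng: np.random.Generator, drift: np.ndarray
) -> list[pd.DataFrame]:
    rows = []
    frames = np.arange(config.n_frames)
    times = config.times()
    for b, (bx, by) in enumerate(config.bead_positions):
        base = np.column_stack([np.full(config.n_frames, bx), np.full(config.n_frames, by)])
        true = base + drift
        red_obs = true + rng.normal(0.0, config.localization_sd, size=true.shape)
        far_obs = config.channel_transform.apply(true) + rng.normal(
            0.0, config.localization_sd, size=true.shape
        )
        for channel, obs in (("red", red_obs), ("far_red", far_obs)):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "time_s": times,
                        "channel": channel,
                        "object_id": f"bead{b}",
                        "role": "bead",
                        "x_nm": obs[:, 0],
                        "y_nm": obs[:, 1],
                        "intensity": np.nan,
                        "vertex": 0,
                    }
                )
            )
    return rows


def _assemble(rows: list[pd.DataFrame]) -> pd.DataFrame:
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(
        ["frame", "channel", "role", "object_id", "vertex"], ignore_index=True
    )
    return table[TRACK_COLUMNS]


def generate_helical_event(
    config: SceneConfig, event_id: str = "event0"
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one helically sliding transport microtubule plus scene context.

    The transport center advances as ``s(t) = s0 + v t`` while its azimuth
    advances by 2 pi per pitch of forward motion (sign set by handedness).
    While any part of the transport footprint overlaps a ridge interval the
    azimuth is clamped to the ridge-locked side.  Template polyline (red
    channel), fiducial beads (both channels) and the transport point
    (far-red channel, mapped through the channel distortion) are emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    drift = np.outer(np.arange(config.n_frames), np.asarray(config.drift_rate, dtype=float))

    t = config.times()
    s = config.start_position + config.sliding_velocity * t
    sign = _PHASE_SIGN[config.handedness]
    phi = config.initial_phase + sign * 2.0 * np.pi * (s - s[0]) / config.helical_pitch
    on_ridge = _footprint_on_ridge(s, config.transport_length / 2.0, config.ridge_intervals)
    # clamp: right-handed (sign=-1) -> phi=-pi/2 -> sideways -R (right-hand side)
    phi = np.where(on_ridge, sign * np.pi / 2.0, phi)
    true_xy = np.column_stack([s, config.helical_radius * np.sin(phi)]) + drift

    rows = _template_rows(config, rng, drift)
    rows += _bead_rows(config, rng, drift)
    transport_obs = config.channel_transform.apply(true_xy) + rng.normal(
        0.0, config.localization_sd, size=true_xy.shape
    )
    rows.append(
        pd.DataFrame(
            {
                "frame": np.arange(config.n_frames),
                "time_s": t,
                "channel": "far_red",
                "object_id": event_id,
                "role": "transport",
                "x_nm": transport_obs[:, 0],
                "y_nm": transport_obs[:, 1],
                "intensity": np.nan,
                "vertex": 0,
            }
        )
    )
    truth = GroundTruth(
        event_id=event_id,
        true_pitch=config.helical_pitch,
        true_diameter=config.helical_diameter,
        true_velocity=config.sliding_velocity,
        true_handedness=config.handedness,
        true_period_s=config.helical_pitch / config.sliding_velocity,
        true_channel_transform=config.channel_transform.inverse(),
        true_drift_rate=tuple(config.drift_rate),
    )
    return _assemble(rows), truth


def generate_parallel_event(
    config: SceneConfig,
    event_id: str = "parallel0",
    azimuth: float | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a longitudinally locked (parallel) transport microtubule.

    The azimuth is drawn once, uniformly on [0, 2 pi), and held fixed; the
    sideways distance is ``R * sin(azimuth)`` plus noise.  Longitudinal
    motion is jitter only, guaranteed below 300 nm over the event.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    drift = np.outer(np.arange(config.n_frames), np.asarray(config.drift_rate, dtype=float))
    theta = float(rng.uniform(0.0, 2.0 * np.pi)) if azimuth is None else float(azimuth)

    t = config.times()
    jitter = np.clip(rng.normal(0.0, 20.0, size=config.n_frames), -140.0, 140.0)
    s = config.start_position + jitter
    true_xy = np.column_stack(
        [s, np.full(config.n_frames, config.helical_radius * np.sin(theta))]
    ) + drift

    rows = _template_rows(config, rng, drift)
    rows += _bead_rows(config, rng, drift)
    transport_obs = config.channel_transform.apply(true_xy) + rng.normal(
        0.0, config.localization_sd, size=true_xy.shape
    )
    rows.append(
        pd.DataFrame(
            {
                "frame": np.arange(config.n_frames),
                "time_s": t,
                "channel": "far_red",
                "object_id": event_id,
                "role": "transport",
                "x_nm": transport_obs[:, 0],
                "y_nm": transport_obs[:, 1],
                "intensity": np.nan,
                "vertex": 0,
            }
        )
    )
    truth = GroundTruth(
        event_id=event_id,
        true_pitch=float("nan"),
        true_diameter=config.helical_diameter,
        true_velocity=0.0,
        true_handedness="undetermined",
        true_period_s=float("nan"),
        true_channel_transform=config.channel_transform.inverse(),
        true_drift_rate=tuple(config.drift_rate),
        true_azimuth=theta,
    )
    return _assemble(rows), truth


def generate_speckle_trace(
    config: SceneConfig, trace_id: str = "speckle0"
) -> tuple[pd.DataFrame, GroundTruth]:
    """Periodically modulated speckle intensity trace from a rotating microtubule.

    ``I(t) = I0 * (1 + m * sin(2 pi t / T + phi0)) + noise`` with rotation
    period ``T = pitch / velocity``.  A period of two frames or less is
    rejected (aliasing).  ``modulation_depth = 0`` emulates a non-rotating
    microtubule (no periodicity).
    """
    config.validate()
    period = config.helical_pitch / config.sliding_velocity
    if not np.isfinite(period) or period <= 2.0 * config.frame_interval:
        raise ValueError(
            f"rotation period {period:.3g} s is at or below the Nyquist limit "
            f"of 2 frames ({2 * config.frame_interval:.3g} s)"
        )
    rng = np.random.default_rng(config.rng_seed)
    t = config.times()
    intensity = config.intensity_baseline * (
        1.0 + config.modulation_depth * np.sin(2.0 * np.pi * t / period + config.initial_phase)
    )
    if config.intensity_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.intensity_noise_sd, size=t.shape)
    intensity = np.clip(intensity, 0.0, None)
    trace = pd.DataFrame({"trace_id": trace_id, "time_s": t, "intensity": intensity})
    truth = GroundTruth(
        event_id=trace_id,
        true_pitch=config.helical_pitch,
        true_diameter=config.helical_diameter,
        true_velocity=config.sliding_velocity,
        true_handedness=config.handedness,
        true_period_s=period,
        true_channel_transform=config.channel_transform.inverse(),
        true_drift_rate=tuple(config.drift_rate),
    )
    return trace, truth


def generate_cohort(
    base_config: SceneConfig,
    n_events: int,
    pitch_range: tuple[float, float] = (500.0, 3000.0),
    seed: int = 0,
    kind: str = "helical",
) -> list[tuple[pd.DataFrame, GroundTruth]]:
    """Generate a cohort of independent events with pitches drawn uniformly.

    Each event gets an independent child seed derived from ``seed`` and, for
    helical events, a pitch drawn uniformly from ``pitch_range`` (the range
    observed across sliding events in this assay geometry).
    """
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_events):
        cfg = dataclasses.replace(
            base_config,
            rng_seed=int(master.integers(0, 2**31 - 1)),
        )
        if kind == "helical":
            cfg = dataclasses.replace(
                cfg, helical_pitch=float(master.uniform(*pitch_range))
            )
            out.append(generate_helical_event(cfg, event_id=f"event{i:03d}"))
        elif kind == "parallel":
            out.append(generate_parallel_event(cfg, event_id=f"parallel{i:03d}"))
        else:
            raise ValueError(f"unknown cohort kind {kind!r}")
    return out
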