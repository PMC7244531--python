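"""Per-rotation helical pitch, diameter, velocity and handedness extraction.

A helically sliding transport microtubule traces a sinusoidal sideways
distance x(s) against the longitudinal coordinate s.  This module automates
what is otherwise a manual measurement: local extrema of x(s) are detected
on the smoothed trace (valley regions only), refined by local quadratic
fits, and paired into rotations.  Per rotation,

* pitch   = arc length between successive same-type extrema (one full
  period; robust to waveform asymmetry),
* diameter = mean peak-to-peak |x_max - x_min| over the two adjacent
  opposite-type pairs.

Event-level values are the averages over rotations.  Handedness follows
from the ridge-locking rule: transport microtubules pinned on the
right-hand side (negative mean sideways distance over ridge frames)
indicate right-handed helical motion.  The 2D projection alone (a
sinusoid) carries no chirality information, so events without ridge frames
are reported as undetermined.

The contour velocity converts the end-to-end speed into the speed along
the 3D helical path, sqrt(v^2 + (v / pitch * 2 pi r)^2), with the helix
radius r = 43 nm by default (25 nm microtubules + 18 nm motor extension).
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

__all__ = [
    "HelixMeasurement",
    "Velocity",
    "detect_extrema",
    "measure_rotations",
    "end_to_end_velocity",
    "contour_velocity",
    "infer_handedness",
    "analyze_event",
    "DEFAULT_HELIX_RADIUS_NM",
]

DEFAULT_HELIX_RADIUS_NM = 43.0

EXTREMA_COLUMNS = ["segment", "s_nm", "x_nm", "kind"]
ROTATION_COLUMNS = ["segment", "s_start_nm", "s_end_nm", "pitch_nm", "diameter_nm"]


class Velocity(NamedTuple):
    """End-to-end speed with motion-direction flag (+1 toward increasing s)."""

    magnitude: float
    direction: int


@dataclasses.dataclass
class HelixMeasurement:
    """Event-level helix parameters plus the per-rotation table."""

    event_id: str
    n_rotations: int
    pitch_nm: float
    pitch_sd_nm: float
    diameter_nm: float
    velocity_nm_s: float
    contour_velocity_nm_s: float
    handedness: str
    rotational_frequency_hz: float
    rotations: pd.DataFrame = dataclasses.field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "event_id": self.event_id,
            "n_rotations": self.n_rotations,
            "pitch_nm": self.pitch_nm,
            "pitch_sd_nm": self.pitch_sd_nm,
            "diameter_nm": self.diameter_nm,
            "velocity_nm_s": self.velocity_nm_s,
            "contour_velocity_nm_s": self.contour_velocity_nm_s,
            "handedness": self.handedness,
            "rot_freq_hz": self.rotational_frequency_hz,
        }


def _robust_noise_sd(x: np.ndarray) -> float:
    """Localization-noise scale from the MAD of second differences.

    Second differences suppress the smooth sinusoidal signal while
    amplifying white noise by sqrt(6).
    """
    if len(x) < 3:
        return 0.0
    d2 = np.diff(x, n=2)
    return 1.4826 * float(np.median(np.abs(d2))) / math.sqrt(6.0)


def _spectral_period(s: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Dominant period of x(s) and its peak-to-median power ratio.

    The trace is resampled onto a uniform s grid; the spectral peak is
    refined by parabolic interpolation on log power.
    """
    span = s[-1] - s[0]
    n = len(s)
    if span <= 0 or n < 8:
        return float("nan"), 0.0
    grid = np.linspace(s[0], s[-1], n)
    xi = np.interp(grid, s, x)
    xi = xi - xi.mean()
    power = np.abs(np.fft.rfft(xi)) ** 2
    if len(power) < 3:
        return float("nan"), 0.0
    power = power[1:]  # drop DC
    k = int(np.argmax(power))
    med = float(np.median(power))
    ratio = float(power[k] / med) if med > 0 else float("inf")
    # parabolic refinement in bin index
    kk = k
    if 0 < k < len(power) - 1:
        y0, y1, y2 = np.log(power[k - 1 : k + 2] + 1e-300)
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            kk = k + 0.5 * (y0 - y2) / denom
    freq = (kk + 1) / span  # cycles per nm (bins start at 1/span)
    return 1.0 / freq, ratio


def _quadratic_refine(
    s: np.ndarray, x: np.ndarray, s0: float, half_width: float, kind: str
) -> tuple[float, float]:
    """Refine an extremum by a local quadratic fit around s0.

    The refined position is the parabola vertex (when the curvature has the
    expected sign and the vertex stays inside the window); the refined
    value is the fitted polynomial evaluated AT s0, which is linear in the
    data and therefore unbiased under noise (a vertex value would inherit
    a max-of-noise bias).  Falls back to the nearest sample when the
    window holds fewer than 3 points.
    """
    mask = np.abs(s - s0) <= half_width
    if mask.sum() < 3:
        i = int(np.argmin(np.abs(s - s0)))
        return float(s[i]), float(x[i])
    ss, xx = s[mask] - s0, x[mask]
    a, b, c = np.polyfit(ss, xx, 2)
    s_ref = s0
    want_max = kind == "max"
    if (want_max and a < 0) or (not want_max and a > 0):
        vertex = -b / (2 * a)
        if abs(vertex) <= half_width:
            s_ref = s0 + vertex
    return float(s_ref), float(c)


def _enforce_alternation(extrema: list[tuple[float, float, str, float]]):
    """Drop the lower-prominence member of any same-type adjacent pair."""
    changed = True
    while changed and len(extrema) > 1:
        changed = False
        for i in range(len(extrema) - 1):
            if extrema[i][2] == extrema[i + 1][2]:
                drop = i if extrema[i][3] < extrema[i + 1][3] else i + 1
                extrema.pop(drop)
                changed = True
                break
    return extrema


def detect_extrema(
    event: pd.DataFrame,
    min_prominence: float | None = None,
    min_separation: float | None = None,
    prominence_factor: float = 3.0,
    separation_factor: float = 0.7,
    snr_gate: float = 10.0,
    smoothing_window: int = 20,
) -> pd.DataFrame:
    """Alternating maxima/minima of the sideways distance x(s), valley regions only.

    Each contiguous valley run is treated as an independent segment
    (rotations never span a ridge).  A segment is considered rotating when
    the dominant spectral peak of x(s) stands above the median spectral
    power by ``snr_gate`` and its amplitude exceeds ``prominence_factor``
    times the (MAD-based) noise level of the smoothed trace.  Same-type
    extrema are separated by at least ``min_separation`` (default
    ``separation_factor`` times the dominant period — same-type extrema sit
    one full pitch apart).  Positions are refined by quadratic fits to the
    smoothed trace, amplitudes by quadratic fits to the raw trace, so that
    amplitudes are not biased by the 20-frame display smoothing.

    Returns a DataFrame ``segment, s_nm, x_nm, kind`` ordered by s; an
    empty frame marks a non-rotating event.
    """
    if "x_smooth_nm" not in event.columns:
        from .geometry import smooth_event

        event = smooth_event(event, window=min(smoothing_window, len(event)))
    window = event.attrs.get("smoothing_window", smoothing_window)
    records: list[tuple[int, float, float, str]] = []
    valley = (event["region"] == "valley").to_numpy()
    seg_ids = np.cumsum(np.concatenate([[0], np.abs(np.diff(valley.astype(int)))]))
    for seg in np.unique(seg_ids[valley]):
        rows = event[(seg_ids == seg) & valley]
        if len(rows) < 8:
            continue
        order = np.argsort(rows["s_nm"].to_numpy(), kind="stable")
        s = rows["s_nm"].to_numpy()[order]
        x_raw = rows["x_nm"].to_numpy()[order]
        ds = np.median(np.abs(np.diff(s)))
        if not np.isfinite(ds) or ds <= 0:
            continue
        period, ratio = _spectral_period(s, x_raw)
        if not np.isfinite(period) or (s[-1] - s[0]) < 1.5 * period:
            continue
        sigma = _robust_noise_sd(x_raw)
        grid = np.linspace(s[0], s[-1], len(s))
        xi = np.interp(grid, s, x_raw)
        amp = 2.0 * np.abs(np.fft.rfft(xi - xi.mean())).max() / len(xi)
        floor = prominence_factor * sigma / math.sqrt(max(window, 1))
        if ratio < snr_gate or amp < max(floor, 1e-9):
            continue
        sep = (
            min_separation
            if min_separation is not None
            else separation_factor * period
        )
        distance = max(1, int(round(sep / ds)))
        # detection smoothing: never wider than ~1/6 period, else short-pitch
        # events are attenuated and their extrema displaced
        w_det = max(1, min(window, int(round(period / (6.0 * ds)))))
        x_sm = (
            pd.Series(x_raw).rolling(w_det, center=True, min_periods=1).mean().to_numpy()
        )
        found: list[tuple[float, float, str, float]] = []
        for sign, kind in ((1.0, "max"), (-1.0, "min")):
            peaks, props = find_peaks(
                sign * x_sm, distance=distance, prominence=min_prominence
            )
            if "prominences" in props:
                proms = props["prominences"]
            elif len(peaks):
                proms = peak_prominences(sign * x_sm, peaks)[0]
            else:
                proms = np.empty(0)
            for p, pr in zip(peaks, proms):
                found.append((float(s[p]), float(x_sm[p]), kind, float(pr)))
        found.sort(key=lambda rec: rec[0])
        found = _enforce_alternation(found)
        for s0, _, kind, _ in found:
            s_ref, _ = _quadratic_refine(s, x_sm, s0, period / 8.0, kind)
            _, x_ref = _quadratic_refine(s, x_raw, s_ref, period / 12.0, kind)
            records.append((int(seg), s_ref, x_ref, kind))
    extrema = pd.DataFrame(records, columns=EXTREMA_COLUMNS)
    extrema = extrema.sort_values(["segment", "s_nm"], ignore_index=True)
    if len(extrema) < 2:
        return extrema.iloc[0:0]
    return extrema


def measure_rotations(extrema: pd.DataFrame) -> pd.DataFrame:
    """Per-rotation pitch and diameter from an alternating extrema list.

    One rotation is a same-type extremum triple (max-min-max or
    min-max-min): its pitch is the arc length between the outer pair and
    its diameter the mean |x_max - x_min| over the two inner opposite-type
    pairs.  Rotations never span segment (ridge) boundaries; edge rotations
    with partial extrema are excluded by construction.
    """
    rows = []
    for seg, grp in extrema.groupby("segment"):
        s = grp["s_nm"].to_numpy()
        x = grp["x_nm"].to_numpy()
        kind = grp["kind"].to_numpy()
        for i in range(len(grp) - 2):
            if kind[i] != kind[i + 2] or kind[i] == kind[i + 1]:
                continue
            pitch = s[i + 2] - s[i]
            diameter = 0.5 * (abs(x[i] - x[i + 1]) + abs(x[i + 1] - x[i + 2]))
            rows.append((seg, s[i], s[i + 2], pitch, diameter))
    return pd.DataFrame(rows, columns=ROTATION_COLUMNS)


def end_to_end_velocity(event: pd.DataFrame) -> Velocity:
    """Endpoint speed |s_last - s_first| / (t_last - t_first), with direction."""
    t0, t1 = event["time_s"].iloc[0], event["time_s"].iloc[-1]
    if len(event) < 2 or t1 <= t0:
        raise ValueError("end-to-end velocity undefined for a single-frame event")
    ds = event["s_nm"].iloc[-1] - event["s_nm"].iloc[0]
    v = ds / (t1 - t0)
    return Velocity(abs(float(v)), 1 if v >= 0 else -1)


def contour_velocity(
    velocity: float, pitch: float, r: float = DEFAULT_HELIX_RADIUS_NM
) -> float:
    """Speed along the 3D helical path: sqrt(v^2 + (v / pitch * 2 pi r)^2)."""
    if np.isinf(pitch):
        return float(velocity)
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if velocity < 0:
        raise ValueError("velocity must be >= 0")
    return float(math.hypot(velocity, velocity / pitch * 2.0 * math.pi * r))


def infer_handedness(
    event: pd.DataFrame, min_ridge_frames: int = 10, z: float = 3.0
) -> str:
    """Chirality from the ridge-locking rule.

    Over ridge-region frames a right-handed event is pinned on the
    right-hand side (negative mean sideways distance).  The call returns
    'undetermined' when there are too few ridge frames or the mean is not
    significantly different from zero — a 1D sinusoidal projection without
    ridge locking carries no chirality information.
    """
    ridge = event[event["region"] == "ridge"]
    if len(ridge) < min_ridge_frames:
        return "undetermined"
    x = ridge["x_nm"].to_numpy()
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    if sem > 0 and abs(mean) < z * sem:
        return "undetermined"
    return "right" if mean < 0 else "left"


def analyze_event(
    event: pd.DataFrame,
    r: float = DEFAULT_HELIX_RADIUS_NM,
    min_turns: int = 2,
    **extrema_kwargs,
) -> HelixMeasurement:
    """Full per-event helix measurement.

    Pitch and diameter are means over complete rotations; the diameter is
    reported only for events with at least ``min_turns`` complete turns.
    Velocity is endpoint-based over the whole event; the rotational
    frequency is velocity / pitch.
    """
    event_id = str(event["event_id"].iloc[0]) if "event_id" in event.columns else ""
    extrema = detect_extrema(event, **extrema_kwargs)
    rotations = measure_rotations(extrema)
    n_rot = len(rotations)
    vel = end_to_end_velocity(event)
    if n_rot >= 1:
        pitch = float(rotations["pitch_nm"].mean())
        pitch_sd = float(rotations["pitch_nm"].std(ddof=1)) if n_rot > 1 else float("nan")
        cv = contour_velocity(vel.magnitude, pitch, r=r)
        freq = vel.magnitude / pitch
    else:
        pitch = pitch_sd = cv = freq = float("nan")
    diameter = float(rotations["diameter_nm"].mean()) if n_rot >= min_turns else float("nan")
    return HelixMeasurement(
        event_id=event_id,
        n_rotations=n_rot,
        pitch_nm=pitch,
        pitch_sd_nm=pitch_sd,
        diameter_nm=diameter,
        velocity_nm_s=vel.magnitude,
        contour_velocity_nm_s=cv,
        handedness=infer_handedness(event),
        rotational_frequency_hz=freq,
        rotations=rotations,
    )
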