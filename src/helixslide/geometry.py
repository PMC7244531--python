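"""Template centerline averaging and signed sideways-distance geometry.

The template microtubule is immobilized, so its tracked polyline is averaged
over the recorded frames (after arc-length resampling to a common vertex
count) to obtain a low-noise centerline.  Transport-microtubule center
points are then expressed in centerline coordinates: the longitudinal
position is the arc length of the projection foot, and the sideways
distance is the perpendicular distance to the polyline, signed positive on
the LEFT of the centerline orientation (the direction of transport motion,
toward the template minus-end).

Point-to-polyline projection is delegated to shapely; the sign is computed
from the cross product of the local segment direction with the
foot-to-point vector.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString

__all__ = [
    "Centerline",
    "average_centerline",
    "sideways_distance",
    "longitudinal_position",
    "build_event",
    "smooth_event",
]


@dataclasses.dataclass
class Centerline:
    """Averaged template polyline with orientation and ridge/valley regions.

    ``vertices`` are ordered along the orientation (direction of transport
    motion); arc length is zero at the first vertex and strictly increasing.
    ``ridge_intervals`` are half-open arc-length intervals [lo, hi) labeled
    'ridge'; everything else is 'valley'.
    """

    vertices: np.ndarray
    ridge_intervals: tuple[tuple[float, float], ...] = ()
    orientation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("centerline needs at least 2 (x, y) vertices")
        seg = np.diff(self.vertices, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len == 0):
            raise ValueError("consecutive centerline vertices must be distinct")
        if self.orientation is not None:
            chord = self.vertices[-1] - self.vertices[0]
            if float(np.dot(chord, np.asarray(self.orientation))) < 0:
                self.vertices = self.vertices[::-1].copy()
                seg = np.diff(self.vertices, axis=0)
                seg_len = np.hypot(seg[:, 0], seg[:, 1])
        self._seg_dirs = seg / seg_len[:, None]
        self._cumlen = np.concatenate([[0.0], np.cumsum(seg_len)])
        self._line = LineString(self.vertices)

    @property
    def length(self) -> float:
        return float(self._cumlen[-1])

    def with_ridges(self, ridge_intervals: Sequence[tuple[float, float]]) -> "Centerline":
        return Centerline(
            self.vertices.copy(), tuple(tuple(r) for r in ridge_intervals), self.orientation
        )

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project points onto the polyline.

        Returns ``(s, x, in_span)``: arc length of the projection foot,
        signed sideways distance (positive left of orientation), and a mask
        flagging points whose projection falls within the centerline span
        (overshoot beyond either end of up to one local segment length is
        tolerated; the arc length is then clamped to the span).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        geoms = shapely.points(pts)
        s = shapely.line_locate_point(self._line, geoms)
        feet = shapely.get_coordinates(shapely.line_interpolate_point(self._line, s))
        idx = np.clip(np.searchsorted(self._cumlen[1:], s, side="left"), 0, len(self._seg_dirs) - 1)
        d = self._seg_dirs[idx]
        rel = pts - feet
        # distance to the nearest polyline point; the cross product with the
        # local direction only supplies the side (it understates the
        # magnitude when the foot is a corner vertex)
        mag = np.hypot(rel[:, 0], rel[:, 1])
        cross = d[:, 0] * rel[:, 1] - d[:, 1] * rel[:, 0]
        x = np.where(cross >= 0, mag, -mag)
        # overshoot beyond the clamped endpoints, along the end segments
        v0, vn = self.vertices[0], self.vertices[-1]
        d0, dn = self._seg_dirs[0], self._seg_dirs[-1]
        over_start = -((pts - v0) @ d0)
        over_end = (pts - vn) @ dn
        seg_first = self._cumlen[1] - self._cumlen[0]
        seg_last = self._cumlen[-1] - self._cumlen[-2]
        in_span = (over_start <= seg_first) & (over_end <= seg_last)
        return s, x, in_span

    def region_at(self, s: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """'ridge' where s falls within a ridge interval expanded by ``margin``."""
        s = np.asarray(s, dtype=float)
        ridge = np.zeros(s.shape, dtype=bool)
        for lo, hi in self.ridge_intervals:
            ridge |= (s >= lo - margin) & (s < hi + margin)
        return np.where(ridge, "ridge", "valley")


def _order_frame_polyline(verts: np.ndarray, ref: np.ndarray | None) -> np.ndarray:
    """Flip a frame's digitization order if it is reversed relative to ``ref``."""
    if ref is None:
        return verts
    fwd = np.linalg.norm(verts[0] - ref[0]) + np.linalg.norm(verts[-1] - ref[-1])
    rev = np.linalg.norm(verts[-1] - ref[0]) + np.linalg.norm(verts[0] - ref[-1])
    return verts[::-1] if rev < fwd else verts


def _resample_polyline(verts: np.ndarray, n: int) -> np.ndarray:
    seg = np.diff(verts, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if cum[-1] == 0:
        raise ValueError("degenerate template polyline (zero length)")
    frac = cum / cum[-1]
    grid = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(grid, frac, verts[:, 0]), np.interp(grid, frac, verts[:, 1])])


def average_centerline(
    template_track: pd.DataFrame,
    n_vertices: int | None = None,
    orientation: tuple[float, float] | None = None,
    min_coverage: float = 0.5,
) -> Centerline:
    """Frame-average the tracked template polyline into a centerline.

    Each frame's polyline is normalized in digitization order, resampled at
    uniform arc-length fractions to a common vertex count, and the vertices
    are averaged across frames.  ``orientation`` (unit vector toward the
    template minus-end, i.e. the direction of transport motion) comes from
    event metadata; if omitted the vertex order is taken as the orientation.
    """
    rows = template_track[template_track["role"] == "template"]
    if rows.empty:
        raise ValueError("no template localizations in track table")
    frames = rows.groupby("frame")
    n_total = rows["frame"].nunique()
    all_frames = template_track["frame"].nunique()
    if n_total < min_coverage * all_frames:
        warnings.warn(
            f"template tracked in only {n_total}/{all_frames} frames", stacklevel=2
        )
    polylines = []
    ref = None
    for _, grp in frames:
        grp = grp.sort_values("vertex") if "vertex" in grp.columns else grp
        verts = grp[["x_nm", "y_nm"]].to_numpy()
        if len(verts) < 2:
            raise ValueError("template frame with fewer than 2 vertices")
        verts = _order_frame_polyline(verts, ref)
        if ref is None:
            ref = verts
        polylines.append(verts)
    if n_vertices is None:
        n_vertices = int(np.median([len(p) for p in polylines]))
    stack = np.stack([_resample_polyline(p, n_vertices) for p in polylines])
    return Centerline(stack.mean(axis=0), orientation=orientation)


def sideways_distance(points: np.ndarray, centerline: Centerline) -> np.ndarray:
    """Signed perpendicular distance of points from the centerline (nm).

    Positive values lie to the left of the centerline orientation.
    Out-of-span points return NaN.
    """
    _, x, in_span = centerline.project(points)
    x = np.where(in_span, x, np.nan)
    return x if np.asarray(points).ndim == 2 else float(x[0])


def longitudinal_position(points: np.ndarray, centerline: Centerline) -> np.ndarray:
    """Arc-length coordinate of the projection foot (nm); NaN out of span."""
    s, _, in_span = centerline.project(points)
    s = np.where(in_span, s, np.nan)
    return s if np.asarray(points).ndim == 2 else float(s[0])


def build_event(
    transport_track: pd.DataFrame,
    centerline: Centerline,
    event_id: str | None = None,
    parallel_threshold: float = 300.0,
    outlier_gate: float = 200.0,
    ridge_margin: float = 0.0,
) -> pd.DataFrame:
    """Convert a corrected transport track into a sliding event.

    Returns a DataFrame with columns ``event_id, frame, time_s, s_nm, x_nm,
    region, polarity``.  Out-of-span projections and sideways distances
    beyond ``outlier_gate`` (tracking outliers) are excluded; the excluded
    counts are recorded in ``attrs``.  Polarity is 'parallel' when the net
    longitudinal displacement over the event is below ``parallel_threshold``
    (locked events), otherwise 'antiparallel'.  ``ridge_margin`` expands the
    ridge intervals when labeling frames, to cover frames whose transport
    footprint (rather than center) overlaps a ridge; pass half the transport
    length.
    """
    rows = transport_track[transport_track["role"] == "transport"]
    if event_id is None:
        ids = rows["object_id"].unique()
        if len(ids) != 1:
            raise ValueError("transport track contains multiple object ids; pass event_id")
        event_id = str(ids[0])
    else:
        rows = rows[rows["object_id"] == event_id]
    rows = rows.sort_values("frame")
    s, x, in_span = centerline.project(rows[["x_nm", "y_nm"]].to_numpy())
    keep = in_span & (np.abs(x) <= outlier_gate)
    event = pd.DataFrame(
        {
            "event_id": event_id,
            "frame": rows["frame"].to_numpy()[keep],
            "time_s": rows["time_s"].to_numpy()[keep],
            "s_nm": s[keep],
            "x_nm": x[keep],
            "region": centerline.region_at(s[keep], margin=ridge_margin),
        }
    )
    if len(event) < 2:
        raise ValueError(f"event {event_id!r}: fewer than 2 usable frames")
    net = abs(event["s_nm"].iloc[-1] - event["s_nm"].iloc[0])
    event["polarity"] = "parallel" if net < parallel_threshold else "antiparallel"
    event.attrs["n_out_of_span"] = int((~in_span).sum())
    event.attrs["n_outliers"] = int((in_span & (np.abs(x) > outlier_gate)).sum())
    return event


def smooth_event(event: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Centered rolling-mean smoothing of the sideways and longitudinal series.

    Adds ``x_smooth_nm`` and ``s_smooth_nm`` columns; the raw columns are
    retained (statistics are computed on raw data, smoothing serves extrema
    detection and display).  The window shrinks at the edges; a window
    longer than the event is clipped with a warning.
    """
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    if window > len(event):
        warnings.warn(
            f"smoothing window {window} exceeds event length {len(event)}; clipping",
            stacklevel=2,
        )
        window = len(event)
    out = event.copy()
    roll = out[["x_nm", "s_nm"]].rolling(window, center=True, min_periods=1).mean()
    out["x_smooth_nm"] = roll["x_nm"]
    out["s_smooth_nm"] = roll["s_nm"]
    out.attrs = dict(event.attrs)
    out.attrs["smoothing_window"] = window
    return out
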