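"""Channel registration and drift correction from fiducial bead tracks.

Dual-color assays image the template microtubule (red channel) and the
transport microtubule (far-red channel) through different filter sets, so the
two channels are related by a small nonreflective similarity transform
(translation, rotation, isotropic scaling).  In addition the stage drifts
slowly over the course of a movie.  Both distortions are estimated from
multi-channel fiducial beads and removed before any sideways-distance
geometry is computed.

The transform fit is the closed-form least-squares (Umeyama/Procrustes)
solution restricted to positive determinant, computed on time-averaged,
drift-corrected bead positions.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityTransform",
    "fit_similarity",
    "estimate_channel_transform",
    "estimate_drift",
    "apply_corrections",
    "InsufficientFiducialsError",
]


class InsufficientFiducialsError(ValueError):
    """Raised when fewer than three matched fiducial beads are available."""


@dataclasses.dataclass(frozen=True)
class SimilarityTransform:
    """Nonreflective 2D similarity: ``p -> scale * R(rotation) @ p + translation``.

    Parameters
    ----------
    rotation:
        Rotation angle in radians (counterclockwise).
    scale:
        Isotropic scale factor, strictly positive.
    translation:
        Translation vector in nm.
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive (nonreflective similarity)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @property
    def linear(self) -> np.ndarray:
        """2x2 linear part ``scale * R``; determinant is ``scale**2 > 0``."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + np.asarray(self.translation)
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        rinv = np.array([[c, -s], [s, c]])
        t = -inv_scale * (rinv @ np.asarray(self.translation))
        return SimilarityTransform(-self.rotation, inv_scale, (t[0], t[1]))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        t = self.apply(np.asarray(other.translation))
        return SimilarityTransform(
            self.rotation + other.rotation, self.scale * other.scale, (t[0], t[1])
        )

    def almost_equals(self, other: "SimilarityTransform", tol: float = 1e-9) -> bool:
        da = (self.rotation - other.rotation + math.pi) % (2 * math.pi) - math.pi
        return (
            abs(da) <= tol
            and abs(self.scale - other.scale) <= tol
            and float(np.abs(np.subtract(self.translation, other.translation)).max()) <= tol
        )


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> tuple[SimilarityTransform, float]:
    """Closed-form least-squares nonreflective similarity mapping src onto dst.

    Returns the transform and the residual RMS (nm) of ``dst - T(src)``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matched (N, 2) arrays")
    n = len(src)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    src_c, dst_c = src - mu_s, dst - mu_d
    cov = dst_c.T @ src_c / n
    u, sing, vt = np.linalg.svd(cov)
    if sing[0] > 0 and sing[1] / sing[0] < 1e-12:
        warnings.warn(
            "fiducial beads are (near-)collinear; similarity transform is "
            "still defined but poorly conditioned",
            stacklevel=2,
        )
    d = 1.0 if np.linalg.det(u) * np.linalg.det(vt) > 0 else -1.0
    rot = u @ np.diag([1.0, d]) @ vt
    var_s = (src_c**2).sum() / n
    if var_s == 0:
        raise ValueError("degenerate source points (zero spread)")
    scale = (sing[0] + d * sing[1]) / var_s
    trans = mu_d - scale * rot @ mu_s
    tform = SimilarityTransform(
        rotation=math.atan2(rot[1, 0], rot[0, 0]),
        scale=float(scale),
        translation=(float(trans[0]), float(trans[1])),
    )
    resid = dst - tform.apply(src)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tform, rms


def _bead_rows(tracks: pd.DataFrame, channel: str) -> pd.DataFrame:
    return tracks[(tracks["role"] == "bead") & (tracks["channel"] == channel)]


def estimate_drift(
    tracks: pd.DataFrame, max_missing_frac: float = 0.2
) -> pd.DataFrame:
    """Per-frame, per-channel stage drift from fiducial bead tracks.

    The offset at frame ``k`` is the mean displacement of the beads from
    their positions at the reference frame (the first frame in which the
    channel was imaged), so the offset at the reference frame is (0, 0).
    Beads missing from more than ``max_missing_frac`` of the channel's
    frames (or absent at the reference frame) are excluded with a warning.

    Returns a DataFrame with columns ``frame, channel, dx_nm, dy_nm``.
    """
    out = []
    for channel in sorted(tracks.loc[tracks["role"] == "bead", "channel"].unique()):
        beads = _bead_rows(tracks, channel)
        frames = np.sort(beads["frame"].unique())
        if len(frames) == 0:
            continue
        ref_frame = frames[0]
        n_frames = len(frames)
        kept = []
        for oid, grp in beads.groupby("object_id"):
            if len(grp) < (1.0 - max_missing_frac) * n_frames or ref_frame not in set(
                grp["frame"]
            ):
                warnings.warn(
                    f"bead {oid!r} excluded from drift estimation in channel "
                    f"{channel!r} (missing in too many frames)",
                    stacklevel=2,
                )
                continue
            kept.append(grp)
        if not kept:
            raise ValueError(f"no usable fiducial beads for drift in channel {channel!r}")
        disp = []
        for grp in kept:
            g = grp.set_index("frame")[["x_nm", "y_nm"]]
            ref = g.loc[ref_frame]
            disp.append(g - ref)
        mean_disp = pd.concat(disp).groupby(level=0).mean()
        for frame, row in mean_disp.iterrows():
            out.append((int(frame), channel, float(row["x_nm"]), float(row["y_nm"])))
    drift = pd.DataFrame(out, columns=["frame", "channel", "dx_nm", "dy_nm"])
    return drift.sort_values(["channel", "frame"], ignore_index=True)


def _drift_corrected_bead_means(
    tracks: pd.DataFrame, drift: pd.DataFrame, channel: str
) -> pd.Series:
    beads = _bead_rows(tracks, channel)
    d = drift[drift["channel"] == channel].set_index("frame")[["dx_nm", "dy_nm"]]
    merged = beads.merge(d, left_on="frame", right_index=True, how="inner")
    merged = merged.assign(
        x_nm=merged["x_nm"] - merged["dx_nm"], y_nm=merged["y_nm"] - merged["dy_nm"]
    )
    return merged.groupby("object_id")[["x_nm", "y_nm"]].mean()


def estimate_channel_transform(
    tracks: pd.DataFrame, drift: pd.DataFrame | None = None
) -> tuple[SimilarityTransform, float]:
    """Estimate the color-offset transform mapping far-red onto red coordinates.

    Beads are drift-corrected per channel, time-averaged per bead, matched by
    ``object_id``, and fitted with the closed-form similarity.  Requires at
    least three matched beads.  Returns ``(transform, residual_rms_nm)``.
    """
    if drift is None:
        drift = estimate_drift(tracks)
    red = _drift_corrected_bead_means(tracks, drift, "red")
    farred = _drift_corrected_bead_means(tracks, drift, "far_red")
    common = sorted(set(red.index) & set(farred.index))
    if len(common) < 3:
        raise InsufficientFiducialsError(
            f"insufficient fiducials: {len(common)} matched beads, need >= 3"
        )
    src = farred.loc[common].to_numpy()
    dst = red.loc[common].to_numpy()
    return fit_similarity(src, dst)


def apply_corrections(
    tracks: pd.DataFrame,
    transform: SimilarityTransform,
    drift: pd.DataFrame,
) -> pd.DataFrame:
    """Apply drift correction per channel, then map far-red through ``transform``.

    Roles and ids are preserved.  The returned table carries a ``corrected``
    flag in ``DataFrame.attrs``; correcting an already-corrected table raises,
    because the operation is not idempotent.
    """
    if tracks.attrs.get("corrected", False):
        raise ValueError("track table is already corrected; refusing to correct twice")
    needed = tracks[["frame", "channel"]].drop_duplicates()
    have = set(zip(drift["frame"], drift["channel"]))
    missing = [fc for fc in zip(needed["frame"], needed["channel"]) if fc not in have]
    if missing:
        raise ValueError(f"no drift entry for (frame, channel) = {missing[0]}")
    out = tracks.merge(drift, on=["frame", "channel"], how="left")
    out["x_nm"] = out["x_nm"] - out["dx_nm"]
    out["y_nm"] = out["y_nm"] - out["dy_nm"]
    out = out.drop(columns=["dx_nm", "dy_nm"])
    far = out["channel"] == "far_red"
    if far.any():
        mapped = transform.apply(out.loc[far, ["x_nm", "y_nm"]].to_numpy())
        out.loc[far, "x_nm"] = mapped[:, 0]
        out.loc[far, "y_nm"] = mapped[:, 1]
    out.attrs["corrected"] = True
    return out
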