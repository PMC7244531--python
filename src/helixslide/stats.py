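"""Bootstrap estimation with mu +/- 3 sigma reporting.

Distribution parameters (sideways distances, pitches, helix diameters) are
estimated by resampling: the N measurements are resampled with replacement
N-at-a-time, the median of each resample is taken, and this is repeated
1000 times.  The estimate is the mean mu of the bootstrap distribution,
its error the SD sigma, and intervals are reported as mu +/- 3 sigma
(nominal 99% confidence).

Pitch and diameter summaries pool one value per EVENT (event means), while
sideways-distance summaries pool per-frame points — matching the dual
N-events / n-points reporting convention of these assays.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["BootstrapSummary", "bootstrap_median", "summarize_events"]


@dataclasses.dataclass
class BootstrapSummary:
    """Bootstrap-of-median summary: mu +/- sigma with a 3-sigma interval."""

    estimator: str
    n: int
    reps: int
    mu: float
    sigma: float
    seed: int | None

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mu - 3.0 * self.sigma, self.mu + 3.0 * self.sigma)

    def to_dict(self) -> dict:
        lo, hi = self.interval
        return {
            "estimator": self.estimator,
            "n": self.n,
            "reps": self.reps,
            "mu": self.mu,
            "sigma": self.sigma,
            "ci3sigma": [lo, hi],
            "seed": self.seed,
        }


def bootstrap_median(
    values, reps: int = 1000, seed: int | None = None
) -> BootstrapSummary:
    """Bootstrap the median of a sample (resample with replacement, reps times)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 values")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    medians = np.median(values[idx], axis=1)
    sigma = float(medians.std(ddof=1)) if reps > 1 else 0.0
    return BootstrapSummary(
        estimator="median", n=n, reps=reps, mu=float(medians.mean()), sigma=sigma, seed=seed
    )


def summarize_events(
    measurements: pd.DataFrame,
    field: str,
    reps: int = 1000,
    seed: int | None = None,
    bins: int | np.ndarray = 10,
    min_turns: int | None = None,
) -> tuple[BootstrapSummary, tuple[np.ndarray, np.ndarray]]:
    """Bootstrap summary plus histogram of one per-event quantity.

    Each event contributes exactly once (its event mean), regardless of how
    many frames or rotations it spans.  ``min_turns`` restricts the
    selection to events with at least that many complete rotations (used
    for diameter summaries, which require two full turns).
    """
    df = measurements
    if min_turns is not None:
        df = df[df["n_rotations"] >= min_turns]
    values = df[field].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError(f"fewer than 2 events with finite {field!r}")
    summary = bootstrap_median(values, reps=reps, seed=seed)
    counts, edges = np.histogram(values, bins=bins)
    return summary, (counts, edges)
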