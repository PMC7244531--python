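import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import helixslide as hx

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sinusoid_event(
    pitch=1300.0,
    radius=43.0,
    ds=20.0,
    n_periods=4.0,
    noise_sd=0.0,
    seed=0,
    phase=0.0,
    velocity=100.0,
    event_id="synthA",
):
    """Directly constructed sliding event with sinusoidal sideways distance."""
    rng = np.random.default_rng(seed)
    s = np.arange(0.0, n_periods * pitch + ds / 2, ds)
    x = radius * np.sin(2.0 * np.pi * s / pitch + phase)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=s.shape)
    frames = np.arange(len(s))
    event = pd.DataFrame(
        {
            "event_id": event_id,
            "frame": frames,
            "time_s": s / velocity,
            "s_nm": s,
            "x_nm": x,
            "region": "valley",
        }
    )
    event["polarity"] = "antiparallel"
    return event


@pytest.fixture
def make_sinusoid_event():
    return sinusoid_event


@pytest.fixture
def analyze_generated():
    """Generate a helical event, run the geometry chain, and analyze it."""

    def _run(pitch=1300.0, noise_sd=10.0, seed=0, turns=3.4, ridge_intervals=(), **scene_kw):
        n_frames = max(60, int(turns * pitch / (100.0 * 0.2)))
        cfg = hx.SceneConfig(
            rng_seed=seed,
            helical_pitch=pitch,
            localization_sd=noise_sd,
            n_frames=n_frames,
            ridge_intervals=ridge_intervals,
            bead_positions=(),
            **scene_kw,
        )
        tracks, truth = hx.generate_helical_event(cfg)
        centerline = hx.average_centerline(
            tracks[tracks.role == "template"], orientation=(1.0, 0.0)
        ).with_ridges(ridge_intervals)
        event = hx.build_event(
            tracks[tracks.role == "transport"],
            centerline,
            ridge_margin=cfg.transport_length / 2.0,
        )
        event = hx.smooth_event(event, window=20)
        return hx.analyze_event(event), truth, event

    return _run
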