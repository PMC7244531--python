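"""Channel-transform estimation, drift correction, and their application."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helixslide as hx
from helixslide.registration import InsufficientFiducialsError, fit_similarity

TRIANGLE = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])


def bead_table(red_pts, far_pts, n_frames=5):
    rows = []
    for k in range(n_frames):
        for b, (r, f) in enumerate(zip(red_pts, far_pts)):
            for channel, p in (("red", r), ("far_red", f)):
                rows.append(
                    dict(
                        frame=k,
                        time_s=0.2 * k,
                        channel=channel,
                        object_id=f"bead{b}",
                        role="bead",
                        x_nm=p[0],
                        y_nm=p[1],
                        intensity=np.nan,
                        vertex=0,
                    )
                )
    return pd.DataFrame(rows)


class TestFitSimilarity:
    def test_identity(self):
        tform, rms = fit_similarity(TRIANGLE, TRIANGLE)
        assert tform.almost_equals(hx.SimilarityTransform.identity(), tol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_exact_parameter_recovery(self):
        truth = hx.SimilarityTransform(
            rotation=math.radians(0.5), scale=1.001, translation=(120.0, -80.0)
        )
        tform, rms = fit_similarity(TRIANGLE, truth.apply(TRIANGLE))
        assert tform.almost_equals(truth, tol=1e-9)
        assert rms < 1e-9

    def test_matches_skimage_oracle(self):
        """Closed-form fit agrees with an independent Umeyama implementation."""
        skimage_tf = pytest.importorskip("skimage.transform")
        rng = np.random.default_rng(42)
        src = rng.uniform(-5000, 5000, size=(6, 2))
        dst = hx.SimilarityTransform(0.01, 1.002, (50.0, -30.0)).apply(src)
        dst = dst + rng.normal(0, 5.0, size=dst.shape)
        ours, _ = fit_similarity(src, dst)
        if hasattr(skimage_tf.SimilarityTransform, "from_estimate"):
            oracle = skimage_tf.SimilarityTransform.from_estimate(src, dst)
        else:  # older scikit-image
            oracle = skimage_tf.SimilarityTransform()
            assert oracle.estimate(src, dst)
        assert ours.rotation == pytest.approx(oracle.rotation, abs=1e-9)
        assert ours.scale == pytest.approx(oracle.scale, abs=1e-9)
        np.testing.assert_allclose(ours.translation, oracle.translation, atol=1e-6)

    def test_noisy_recovery_monte_carlo(self):
        """With 5 nm per-frame noise and time-averaged beads (as the module
        operates), the recovered transform stays within +/-10 nm translation
        and +/-0.2 degree rotation across 100 seeded trials."""
        distortion = hx.SimilarityTransform(
            rotation=math.radians(0.5), scale=1.001, translation=(120.0, -80.0)
        )
        correction = distortion.inverse()
        rng = np.random.default_rng(0)
        ok_t = ok_r = 0
        n_frames = 50
        for _ in range(100):
            rows = []
            for k in range(n_frames):
                red = TRIANGLE + rng.normal(0, 5.0, size=(3, 2))
                far = distortion.apply(TRIANGLE) + rng.normal(0, 5.0, size=(3, 2))
                for b in range(3):
                    for channel, p in (("red", red[b]), ("far_red", far[b])):
                        rows.append(
                            dict(frame=k, time_s=0.2 * k, channel=channel,
                                 object_id=f"bead{b}", role="bead",
                                 x_nm=p[0], y_nm=p[1], intensity=np.nan, vertex=0)
                        )
            tform, _ = hx.estimate_channel_transform(pd.DataFrame(rows))
            if np.abs(np.subtract(tform.translation, correction.translation)).max() <= 10.0:
                ok_t += 1
            if abs(math.degrees(tform.rotation - correction.rotation)) <= 0.2:
                ok_r += 1
        assert ok_t >= 95
        assert ok_r >= 95

    def test_collinear_beads_warn(self):
        src = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        with pytest.warns(UserWarning, match="collinear"):
            fit_similarity(src, src + 5.0)

    @settings(max_examples=30)
    @given(
        rot=st.floats(-math.pi, math.pi),
        scale=st.floats(0.5, 2.0),
        tx=st.floats(-1e4, 1e4),
        ty=st.floats(-1e4, 1e4),
    )
    def test_inverse_roundtrip(self, rot, scale, tx, ty):
        """compose(T, inverse(T)) maps any test point to itself within 1e-9 nm."""
        tform = hx.SimilarityTransform(rot, scale, (tx, ty))
        pts = np.array([[0.0, 0.0], [123.0, -456.0], [9999.0, 1.0]])
        roundtrip = tform.compose(tform.inverse()).apply(pts)
        np.testing.assert_allclose(roundtrip, pts, atol=1e-9)
        assert np.linalg.det(tform.linear) > 0


class TestEstimateChannelTransform:
    def test_identical_beads_identity(self):
        tracks = bead_table(TRIANGLE, TRIANGLE)
        tform, rms = hx.estimate_channel_transform(tracks)
        assert tform.almost_equals(hx.SimilarityTransform.identity(), tol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_correction_transform(self):
        distortion = hx.SimilarityTransform(0.003, 1.0008, (100.0, -50.0))
        tracks = bead_table(TRIANGLE, distortion.apply(TRIANGLE))
        tform, _ = hx.estimate_channel_transform(tracks)
        assert tform.almost_equals(distortion.inverse(), tol=1e-9)

    def test_insufficient_fiducials(self):
        tracks = bead_table(TRIANGLE[:2], TRIANGLE[:2])
        with pytest.raises(InsufficientFiducialsError, match="insufficient fiducials"):
            hx.estimate_channel_transform(tracks)


class TestEstimateDrift:
    def test_stationary_beads_zero_offset(self):
        tracks = bead_table(TRIANGLE, TRIANGLE, n_frames=10)
        drift = hx.estimate_drift(tracks)
        np.testing.assert_allclose(drift[["dx_nm", "dy_nm"]], 0.0, atol=1e-12)

    def test_linear_drift_recovered_exactly(self):
        cfg = hx.SceneConfig(
            rng_seed=0, localization_sd=0.0, drift_rate=(0.5, -0.3), n_frames=50
        )
        tracks, _ = hx.generate_helical_event(cfg)
        drift = hx.estimate_drift(tracks)
        red = drift[drift.channel == "red"].sort_values("frame")
        np.testing.assert_allclose(red.dx_nm, 0.5 * np.arange(50), atol=1e-9)
        np.testing.assert_allclose(red.dy_nm, -0.3 * np.arange(50), atol=1e-9)

    def test_noisy_drift_error_matches_sem(self, rng):
        """Per-frame offset error SD ~ noise_sd / sqrt(n_beads)."""
        n_frames, sd = 400, 5.0
        pts = TRIANGLE
        rows = []
        for k in range(n_frames):
            obs = pts + rng.normal(0, sd, size=pts.shape)
            for b, p in enumerate(obs):
                rows.append(
                    dict(frame=k, time_s=0.2 * k, channel="red", object_id=f"bead{b}",
                         role="bead", x_nm=p[0], y_nm=p[1], intensity=np.nan, vertex=0)
                )
        drift = hx.estimate_drift(pd.DataFrame(rows))
        err = drift[drift.frame > 0][["dx_nm", "dy_nm"]].to_numpy()
        # offset at frame k carries frame-0 and frame-k bead-mean noise
        expected = sd / math.sqrt(3) * math.sqrt(2)
        assert err.std() == pytest.approx(expected, rel=0.25)

    def test_mostly_missing_bead_excluded(self):
        tracks = bead_table(TRIANGLE, TRIANGLE, n_frames=10)
        drop = (tracks.object_id == "bead0") & (tracks.frame > 2)
        with pytest.warns(UserWarning, match="excluded"):
            drift = hx.estimate_drift(tracks[~drop])
        assert len(drift[drift.channel == "red"]) == 10


class TestApplyCorrections:
    def test_identity_is_noop(self):
        tracks = bead_table(TRIANGLE, TRIANGLE)
        drift = hx.estimate_drift(tracks)
        out = hx.apply_corrections(tracks, hx.SimilarityTransform.identity(), drift)
        np.testing.assert_allclose(out[["x_nm", "y_nm"]], tracks[["x_nm", "y_nm"]], atol=1e-12)

    def test_double_correction_guarded(self):
        tracks = bead_table(TRIANGLE, TRIANGLE)
        drift = hx.estimate_drift(tracks)
        out = hx.apply_corrections(tracks, hx.SimilarityTransform.identity(), drift)
        with pytest.raises(ValueError, match="already corrected"):
            hx.apply_corrections(out, hx.SimilarityTransform.identity(), drift)

    def test_missing_drift_entry_raises(self):
        tracks = bead_table(TRIANGLE, TRIANGLE)
        drift = hx.estimate_drift(tracks)
        with pytest.raises(ValueError, match="no drift entry"):
            hx.apply_corrections(tracks, hx.SimilarityTransform.identity(), drift.iloc[:-1])

    def test_corrected_beads_residual_at_noise_level(self):
        """After correction, bead scatter is at the localization-noise scale."""
        sd = 5.0
        cfg = hx.SceneConfig(
            rng_seed=1,
            localization_sd=sd,
            drift_rate=(0.4, -0.25),
            n_frames=200,
            channel_transform=hx.SimilarityTransform(0.002, 1.0005, (80.0, -40.0)),
        )
        tracks, _ = hx.generate_helical_event(cfg)
        drift = hx.estimate_drift(tracks)
        tform, _ = hx.estimate_channel_transform(tracks, drift)
        corrected = hx.apply_corrections(tracks, tform, drift)
        beads = corrected[corrected.role == "bead"]
        resid = beads.groupby(["channel", "object_id"])[["x_nm", "y_nm"]].transform(
            lambda c: c - c.mean()
        )
        assert resid.to_numpy().std() == pytest.approx(sd, rel=0.3)
        # and corrections never increase the bead residual
        raw = tracks[tracks.role == "bead"]
        raw_resid = raw.groupby(["channel", "object_id"])[["x_nm", "y_nm"]].transform(
            lambda c: c - c.mean()
        )
        assert resid.to_numpy().std() <= raw_resid.to_numpy().std() + 1e-9
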