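"""Centerline averaging and signed point-to-polyline geometry."""

import numpy as np
import pandas as pd
import pytest

import helixslide as hx
from helixslide.geometry import Centerline


def template_table(polylines):
    """Track table from a list of per-frame (N, 2) vertex arrays."""
    rows = []
    for k, verts in enumerate(polylines):
        for v, (x, y) in enumerate(verts):
            rows.append(
                dict(frame=k, time_s=0.2 * k, channel="red", object_id="template0",
                     role="template", x_nm=x, y_nm=y, intensity=np.nan, vertex=v)
            )
    return pd.DataFrame(rows)


def segment_candidates(point, verts):
    """Independent per-segment closed-form projection: list of (dist, s)."""
    out = []
    cum = 0.0
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        length = float(np.hypot(*ab))
        t = float(np.clip(np.dot(point - a, ab) / length**2, 0.0, 1.0))
        foot = a + t * ab
        out.append((float(np.hypot(*(point - foot))), cum + t * length))
        cum += length
    return out


class TestAverageCenterline:
    def test_identical_frames_reproduced(self):
        verts = np.array([[0.0, 0.0], [5000.0, 100.0], [10000.0, 0.0]])
        cl = hx.average_centerline(template_table([verts] * 10))
        np.testing.assert_allclose(cl.vertices, verts, atol=1e-9)

    def test_noise_averages_down(self, rng):
        verts = np.column_stack([np.linspace(0, 10000, 21), np.zeros(21)])
        frames = [verts + rng.normal(0, 10.0, size=verts.shape) for _ in range(100)]
        cl = hx.average_centerline(template_table(frames))
        # SE of the mean ~ 10/sqrt(100) = 1 nm per vertex
        assert np.abs(cl.vertices[:, 1]).max() < 4.0

    def test_reversed_digitization_normalized(self):
        verts = np.array([[0.0, 0.0], [5000.0, 50.0], [10000.0, 0.0]])
        frames = [verts, verts[::-1], verts, verts[::-1]]
        cl = hx.average_centerline(template_table(frames))
        np.testing.assert_allclose(cl.vertices, verts, atol=1e-9)

    def test_single_vertex_frame_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            hx.average_centerline(template_table([np.array([[0.0, 0.0]])]))


class TestProjection:
    def test_point_on_centerline_zero(self):
        cl = Centerline(np.array([[0.0, 0.0], [10000.0, 0.0]]))
        assert hx.sideways_distance(np.array([5000.0, 0.0]), cl) == pytest.approx(0.0)

    @pytest.mark.parametrize("y,expected", [(45.5, 45.5), (-45.5, -45.5)])
    def test_sign_convention_left_positive(self, y, expected):
        """Positive sideways distance lies left of the orientation (+x here)."""
        cl = Centerline(np.array([[0.0, 0.0], [10000.0, 0.0]]), orientation=(1.0, 0.0))
        assert hx.sideways_distance(np.array([5000.0, y]), cl) == pytest.approx(expected)
        assert hx.longitudinal_position(np.array([5000.0, y]), cl) == pytest.approx(5000.0)

    def test_orientation_reverses_sign_and_arclength(self):
        cl = Centerline(np.array([[0.0, 0.0], [10000.0, 0.0]]), orientation=(-1.0, 0.0))
        assert hx.sideways_distance(np.array([5000.0, 45.5]), cl) == pytest.approx(-45.5)
        assert hx.longitudinal_position(np.array([5000.0, 45.5]), cl) == pytest.approx(5000.0)

    def test_total_arclength(self):
        cl = Centerline(np.array([[0.0, 0.0], [3000.0, 4000.0], [3000.0, 9000.0]]))
        assert cl.length == pytest.approx(10000.0)

    def test_matches_per_segment_oracle(self, rng):
        """shapely projection equals the closed-form per-segment minimum."""
        for _ in range(200):
            n = rng.integers(2, 8)
            verts = np.cumsum(rng.uniform(-2000, 2000, size=(n + 1, 2)), axis=0)
            if np.any(np.hypot(*np.diff(verts, axis=0).T) < 1.0):
                continue
            cl = Centerline(verts)
            pts = rng.uniform(verts.min() - 500, verts.max() + 500, size=(5, 2))
            s, x, in_span = cl.project(pts)
            for p, si, xi in zip(pts, s, x):
                cands = segment_candidates(p, verts)
                dmin = min(c[0] for c in cands)
                assert abs(xi) == pytest.approx(dmin, abs=1e-6)
                near = [c[1] for c in cands if c[0] <= dmin + 1e-9]
                assert min(abs(si - sc) for sc in near) < 1e-6

    def test_elbow_points(self):
        cl = Centerline(np.array([[0.0, 0.0], [1000.0, 0.0], [1000.0, 1000.0]]))
        # outside the elbow: nearest point is the corner vertex
        s, x, _ = cl.project(np.array([[1100.0, -100.0]]))
        assert abs(x[0]) == pytest.approx(np.hypot(100.0, 100.0), abs=1e-6)
        assert s[0] == pytest.approx(1000.0, abs=1e-6)

    def test_out_of_span_flagged(self):
        cl = Centerline(np.array([[0.0, 0.0], [1000.0, 0.0]]))
        s, x, in_span = cl.project(np.array([[-2500.0, 10.0], [500.0, 10.0]]))
        assert not in_span[0]
        assert in_span[1]
        assert np.isnan(hx.sideways_distance(np.array([[-2500.0, 10.0]]), cl)[0])

    def test_mirror_antisymmetry(self, rng):
        """Mirroring all y negates sideways distances, preserves arc lengths."""
        verts = np.column_stack([np.linspace(0, 8000, 9), rng.uniform(-300, 300, 9)])
        pts = np.column_stack([rng.uniform(500, 7500, 40), rng.uniform(-150, 150, 40)])
        cl = Centerline(verts, orientation=(1.0, 0.0))
        cl_m = Centerline(verts * [1.0, -1.0], orientation=(1.0, 0.0))
        s, x, _ = cl.project(pts)
        s_m, x_m, _ = cl_m.project(pts * [1.0, -1.0])
        np.testing.assert_allclose(s_m, s, atol=1e-9)
        np.testing.assert_allclose(x_m, -x, atol=1e-9)


class TestBuildEvent:
    def transport_table(self, s, x):
        return pd.DataFrame(
            dict(frame=np.arange(len(s)), time_s=0.2 * np.arange(len(s)),
                 channel="far_red", object_id="ev", role="transport",
                 x_nm=s, y_nm=x, intensity=np.nan, vertex=0)
        )

    def test_polarity_classification(self):
        cl = Centerline(np.array([[0.0, 0.0], [10000.0, 0.0]]), orientation=(1.0, 0.0))
        moving = self.transport_table(np.linspace(1000, 5000, 50), np.zeros(50))
        locked = self.transport_table(np.full(50, 3000.0) + np.linspace(0, 100, 50), np.zeros(50))
        assert hx.build_event(moving, cl)["polarity"].iloc[0] == "antiparallel"
        assert hx.build_event(locked, cl)["polarity"].iloc[0] == "parallel"

    def test_outlier_gate_and_region_labels(self):
        cl = Centerline(
            np.array([[0.0, 0.0], [10000.0, 0.0]]), orientation=(1.0, 0.0)
        ).with_ridges([(4000.0, 6000.0)])
        s = np.linspace(1000, 9000, 80)
        x = np.full(80, 40.0)
        x[10] = 500.0  # tracking outlier
        event = hx.build_event(self.transport_table(s, x), cl, ridge_margin=0.0)
        assert event.attrs["n_outliers"] == 1
        assert len(event) == 79
        ridge = event[(event.s_nm >= 4000) & (event.s_nm < 6000)]
        assert (ridge.region == "ridge").all()
        assert (event[event.s_nm < 4000].region == "valley").all()


class TestSmoothEvent:
    def test_window_one_is_identity(self, make_sinusoid_event):
        event = make_sinusoid_event(noise_sd=5.0, seed=1)
        out = hx.smooth_event(event, window=1)
        np.testing.assert_allclose(out.x_smooth_nm, event.x_nm, atol=1e-12)

    def test_constant_signal_unchanged(self, make_sinusoid_event):
        event = make_sinusoid_event()
        event["x_nm"] = 7.0
        out = hx.smooth_event(event, window=20)
        np.testing.assert_allclose(out.x_smooth_nm, 7.0, atol=1e-12)

    def test_noise_variance_reduced_by_window(self, rng):
        n, sigma = 5000, 10.0
        event = pd.DataFrame(
            dict(event_id="e", frame=np.arange(n), time_s=0.2 * np.arange(n),
                 s_nm=np.linspace(0, 1e5, n), x_nm=rng.normal(0, sigma, n),
                 region="valley", polarity="antiparallel")
        )
        out = hx.smooth_event(event, window=20)
        interior = out.x_smooth_nm.to_numpy()[50:-50]
        assert interior.std() == pytest.approx(sigma / np.sqrt(20), rel=0.15)

    def test_oversized_window_clipped(self, make_sinusoid_event):
        event = make_sinusoid_event(n_periods=0.2)
        with pytest.warns(UserWarning, match="clipping"):
            out = hx.smooth_event(event, window=10 * len(event))
        assert out.attrs["smoothing_window"] == len(event)
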