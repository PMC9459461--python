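"""Stimulus synthesis: layouts, drift-rate assignment, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from flowparse import stimulus as st
from flowparse.geometry import drift_axis
from flowparse.stimulus import ObjectMotion


class TestRingLayout:
    def test_equal_angular_spacing(self):
        pts = st.make_ring_layout(28, 4.0)
        assert pts.shape == (28, 2)
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), 4.0)
        ang = np.rad2deg(np.arctan2(pts[:, 0], pts[:, 1]))
        gaps = np.diff(np.sort(np.mod(ang, 360.0)))
        np.testing.assert_allclose(gaps, 360.0 / 28, atol=1e-9)

    def test_single_point_sits_at_vertical(self):
        np.testing.assert_allclose(st.make_ring_layout(1, 2.0), [[0.0, 2.0]], atol=1e-12)

    def test_quarter_turns(self):
        pts = st.make_ring_layout(4, 1.0)
        np.testing.assert_allclose(
            pts, [[0, 1], [1, 0], [0, -1], [-1, 0]], atol=1e-12
        )

    @pytest.mark.parametrize("n", [3, 5, 28])
    def test_rotation_by_one_step_is_a_reindexing(self, n):
        pts = st.make_ring_layout(n, 4.0)
        rotated = st.make_ring_layout(n, 4.0, angular_offset=360.0 / n)
        np.testing.assert_allclose(rotated, np.roll(pts, -1, axis=0), atol=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            st.make_ring_layout(0, 4.0)
        with pytest.raises(ValueError):
            st.make_ring_layout(5, -1.0)


class TestFieldLayout:
    def test_within_extent(self, rng):
        pts = st.make_field_layout(40, (20.0, 20.0), rng)
        assert pts.shape == (40, 2)
        assert np.all(np.abs(pts) <= 10.0)

    def test_degenerate_extent(self, rng):
        np.testing.assert_array_equal(
            st.make_field_layout(1, (0.0, 0.0), rng), [[0.0, 0.0]]
        )

    def test_mean_position_is_central(self, rng):
        pts = st.make_field_layout(10000, (20.0, 20.0), rng)
        assert np.all(np.abs(pts.mean(axis=0)) < 0.3)


class TestDriftRate:
    @pytest.mark.parametrize(
        "orientation,speed,direction,expected",
        [
            (0.0, 6.0, 90.0, 6.0),  # drift axis parallel to motion
            (90.0, 6.0, 90.0, 0.0),  # drift axis orthogonal to motion
            (90.0, 6.0, 30.0, 6.0 * np.cos(np.deg2rad(30.0))),
        ],
    )
    def test_examples(self, orientation, speed, direction, expected):
        rate = st.assign_drift_rate(orientation, ObjectMotion(speed, direction))
        assert rate == pytest.approx(expected, abs=1e-12)

    @given(
        orientation=stn.floats(0.0, 179.999),
        direction=stn.floats(0.0, 360.0, exclude_max=True),
        speed=stn.floats(0.0, 20.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_trigonometry(self, orientation, direction, speed):
        # independent route: signed cosine of the angle between the
        # motion direction and the canonical drift-axis direction
        axis_dir = orientation + 90.0
        v = np.array([np.sin(np.deg2rad(axis_dir)), np.cos(np.deg2rad(axis_dir))])
        if v[0] < -1e-12 or (abs(v[0]) <= 1e-12 and v[1] < 0):
            axis_dir += 180.0
        expected = speed * np.cos(np.deg2rad(direction - axis_dir))
        rate = st.assign_drift_rate(orientation, ObjectMotion(speed, direction))
        assert rate == pytest.approx(expected, abs=1e-9)
        assert abs(rate) <= speed + 1e-9


class TestBuildStimulus:
    def test_field_condition_counts_and_consistency(self, rng):
        spec = st.build_stimulus("exp1-field", background_direction=30.0, rng=rng)
        assert len(spec.target_elements) == 28
        assert len(spec.background_elements) == 40
        for el in spec.elements:
            motion = spec.target_motion if el.owner == "target" else spec.background_motion
            for ori, rate in zip(el.component_orientations, el.drift_rates):
                assert rate == pytest.approx(st.assign_drift_rate(ori, motion), abs=1e-12)

    @pytest.mark.parametrize(
        "condition,n_bg,radius",
        [("exp1-ring", 40, 5.6), ("exp1-ring-inside", 16, 2.4)],
    )
    def test_ring_conditions(self, condition, n_bg, radius, rng):
        spec = st.build_stimulus(condition, background_direction=30.0, rng=rng)
        bg = spec.background_elements
        assert len(bg) == n_bg
        radii = [np.hypot(*el.position) for el in bg]
        np.testing.assert_allclose(radii, radius, atol=1e-9)

    def test_orientation_regimes(self, rng):
        spec = st.build_stimulus("exp3-separated", background_direction=30.0, rng=rng)
        assert {el.orientation for el in spec.background_elements} <= {0.0, 90.0}
        assert {el.orientation for el in spec.target_elements} <= {45.0, 135.0}

    def test_plaid_condition(self, rng):
        spec = st.build_stimulus("exp4-t2d-b1d-outside", background_direction=30.0, rng=rng)
        for el in spec.target_elements:
            assert el.kind == "plaid"
            o1, o2 = el.component_orientations
            assert abs(o1 - o2) % 180.0 == pytest.approx(90.0)
            assert el.component_contrast == pytest.approx(0.20)
        assert all(el.kind == "grating" for el in spec.background_elements)

    def test_spatial_frequency_regimes(self, rng):
        spec = st.build_stimulus("exp2-thigh-blow-inside", background_direction=30.0, rng=rng)
        assert all(el.carrier_sf == 6.0 for el in spec.target_elements)
        assert all(el.carrier_sf == 3.0 for el in spec.background_elements)

    def test_unknown_condition(self):
        with pytest.raises(KeyError):
            st.build_stimulus("exp9-nope", background_direction=0.0, seed=0)

    def test_seed_replay(self):
        a = st.build_stimulus("exp1-field", 30.0, seed=7)
        b = st.build_stimulus("exp1-field", 30.0, seed=7)
        assert a.elements == b.elements


class TestRendering:
    def test_frame_count(self, rng):
        spec = st.build_stimulus("exp1-ring-inside", 30.0, rng=rng,
                                 duration_ms=500.0, frame_rate=100.0)
        assert spec.n_frames == 50

    def test_zero_contrast_is_uniform_grey(self):
        mov = st.render_element(pixels_per_deg=32, n_frames=3, contrast=0.0)
        np.testing.assert_allclose(mov, 0.5, atol=1e-12)

    def test_zero_speed_freezes_the_movie(self):
        mov = st.render_element(pixels_per_deg=32, n_frames=5, speed=0.0)
        for k in range(1, 5):
            np.testing.assert_array_equal(mov[k], mov[0])

    def test_michelson_contrast_of_default_element(self):
        mov = st.render_element(pixels_per_deg=64)
        assert st.michelson_contrast(mov) == pytest.approx(0.40, abs=0.01)

    def test_carrier_frequency_recovered(self):
        frame = st.render_element(pixels_per_deg=64, n_frames=1, window_sds=12)[0]
        bin_width = 64.0 / (12 * 8 / 60 * 64)  # one FFT bin of the unpadded window
        assert st.dominant_spatial_frequency(frame, 64) == pytest.approx(
            3.0, abs=bin_width
        )

    def test_envelope_sd_recovered(self):
        sd = st.estimate_envelope_sd(pixels_per_deg=128)
        assert sd == pytest.approx(8.0, rel=0.05)

    def test_envelope_is_stationary(self):
        # over the full movie only the carrier phase moves, so the
        # per-pixel temporal modulation depth equals contrast * envelope
        mov = st.render_element(pixels_per_deg=64)
        depth = (mov.max(axis=0) - mov.min(axis=0)) / 2.0
        x, y = st._grid_coords((mov.shape[2] / 64.0, mov.shape[1] / 64.0), 64.0)
        rsq = y[:, None] ** 2 + x[None, :] ** 2
        sigma = 8.0 / 60.0
        env = np.exp(-rsq / (2 * sigma**2))
        env[rsq > (3 * sigma) ** 2] = 0.0
        np.testing.assert_allclose(depth, 0.5 * 0.40 * env, atol=0.02)

    def test_overlap_clips_with_warning(self):
        motion = ObjectMotion(0.0, 0.0)
        el = st.make_element((0.0, 0.0), 90.0, motion, "target", contrast=0.9)
        spec = st.StimulusSpec(
            target_elements=[el, el],
            background_elements=[],
            target_motion=motion,
            background_motion=motion,
            duration_ms=10.0,
            frame_rate=100.0,
            field_extent=(1.0, 1.0),
        )
        with pytest.warns(UserWarning, match="clipping"):
            frames = st.render_frames(spec, 64)
        assert frames.max() <= 1.0 and frames.min() >= 0.0

    def test_manifest_columns(self, rng):
        spec = st.build_stimulus("exp4-t2d-b2d-inside", 30.0, rng=rng)
        df = st.element_manifest(spec)
        assert len(df) == 28 + 16
        assert set(df["owner"]) == {"target", "background"}
        assert df.loc[df["kind"] == "plaid", "drift_rate_2"].notna().all()
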