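"""Unit and property tests for the inverse tape model."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tapekin as tk
from tapekin.model import CalibrationError, Flag, PlaneEstimate

L = 1726.0


def ray_oracle(alpha_deg, beta_deg, span=L):
    """Independent evaluation of the ray-intersection formulation."""
    a, b = math.radians(alpha_deg), math.radians(beta_deg)
    t = math.cos(a) + math.sin(a) * math.cos(b) / math.sin(b)
    return math.cos(a) * span / t, -math.sin(a) * span / t


def trig_oracle(alpha_deg, beta_deg, span=L):
    """Independent evaluation of the trigonometric formulation."""
    a, b = math.radians(alpha_deg), math.radians(beta_deg)
    z = -span / (1.0 / math.tan(a) + 1.0 / math.tan(b))
    return abs(z) / math.tan(a), z


class TestEstimateSagittal:
    def test_small_angle_guard_returns_zero(self, geom, params):
        x, z, flags = tk.estimate_sagittal(0.05, 0.05, geom, params)
        assert x[0] == 0.0 and z[0] == 0.0
        assert flags[0] & Flag.LOW_LOAD

    def test_guard_is_strict_less_than(self, geom, params):
        # exactly at the threshold the angles are used
        x, z, flags = tk.estimate_sagittal(0.1, 0.1, geom, params)
        assert flags[0] == 0
        assert z[0] < 0

    def test_symmetric_load_at_midspan(self, geom, params):
        x, z, flags = tk.estimate_sagittal(10.0, 10.0, geom, params)
        assert x[0] == pytest.approx(0.0, abs=1e-9)
        assert z[0] == pytest.approx(-L * math.tan(math.radians(10.0)) / 2.0, abs=1e-9)

    def test_asymmetric_example(self, geom, params):
        x, z, _ = tk.estimate_sagittal(20.0, 10.0, geom, params)
        xo_ray, zo_ray = ray_oracle(20.0, 10.0)
        xo_trig, zo_trig = trig_oracle(20.0, 10.0)
        assert abs(xo_ray - xo_trig) < 1e-9 and abs(zo_ray - zo_trig) < 1e-9
        assert z[0] == pytest.approx(-205.018, abs=1e-2)
        assert x[0] + L / 2 == pytest.approx(563.283, abs=1e-2)  # distance from back anchor
        assert z[0] == pytest.approx(zo_ray, abs=1e-9)

    def test_opposite_signs_flagged_non_numeric(self, geom, params):
        x, z, flags = tk.estimate_sagittal(5.0, -5.0, geom, params)
        assert np.isnan(x[0]) and np.isnan(z[0])
        assert flags[0] & Flag.NO_INTERSECTION

    def test_angle_out_of_range_raises(self, geom, params):
        with pytest.raises(ValueError):
            tk.estimate_sagittal(90.0, 10.0, geom, params)
        with pytest.raises(ValueError):
            tk.estimate_sagittal(np.nan, 10.0, geom, params)

    def test_output_within_anchor_span(self, geom, params):
        a = np.linspace(0.2, 80, 50)
        b = np.linspace(80, 0.2, 50)
        x, z, _ = tk.estimate_sagittal(a, b, geom, params)
        assert np.all(x >= -L / 2) and np.all(x <= L / 2)
        assert np.all(z <= 0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=80.0),
        st.floats(min_value=0.1, max_value=80.0),
    )
    def test_formulations_agree(self, alpha, beta):
        geom = tk.DeviceGeometry()
        x, z, _ = tk.estimate_sagittal(alpha, beta, geom, tk.ModelParams())
        xo, zo = trig_oracle(alpha, beta)
        assert abs((x[0] + L / 2) - xo) < 1e-9 * L
        assert abs(z[0] - zo) < 1e-9 * L

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=80.0),
        st.floats(min_value=0.1, max_value=80.0),
    )
    def test_swap_symmetry(self, alpha, beta):
        geom = tk.DeviceGeometry()
        p = tk.ModelParams()
        x1, z1, _ = tk.estimate_sagittal(alpha, beta, geom, p)
        x2, z2, _ = tk.estimate_sagittal(beta, alpha, geom, p)
        assert z1[0] == pytest.approx(z2[0], abs=1e-9)
        assert x1[0] == pytest.approx(-x2[0], abs=1e-7)  # mirrored about mid-span

    def test_depth_monotone_in_each_angle(self, geom, params):
        alphas = np.linspace(0.2, 79.0, 200)
        _, z, _ = tk.estimate_sagittal(alphas, np.full_like(alphas, 15.0), geom, params)
        assert np.all(np.diff(-z) > 0)
        _, z, _ = tk.estimate_sagittal(np.full_like(alphas, 15.0), alphas, geom, params)
        assert np.all(np.diff(-z) > 0)


class TestEstimateTransversal:
    def test_guard(self, geom, params):
        x, y, flags = tk.estimate_transversal(0.05, 0.05, geom, params)
        assert x[0] == 0.0 and y[0] == 0.0
        assert flags[0] & Flag.LOW_LOAD_TRANSVERSAL

    def test_symmetric(self, geom, params):
        x, y, _ = tk.estimate_transversal(2.0, 2.0, geom, params)
        assert x[0] == pytest.approx(0.0, abs=1e-9)
        assert y[0] == pytest.approx(L * math.tan(math.radians(2.0)) / 2.0, abs=1e-9)

    def test_mirrored_inputs(self, geom, params):
        x1, y1, _ = tk.estimate_transversal(3.0, 1.0, geom, params)
        x2, y2, _ = tk.estimate_transversal(1.0, 3.0, geom, params)
        assert y1[0] == pytest.approx(y2[0], abs=1e-9)
        assert x1[0] == pytest.approx(-x2[0], abs=1e-7)

    def test_negative_pair_is_signed_mirror(self, geom, params):
        x1, y1, _ = tk.estimate_transversal(3.0, 1.0, geom, params)
        x2, y2, _ = tk.estimate_transversal(-3.0, -1.0, geom, params)
        assert y2[0] == pytest.approx(-y1[0], abs=1e-9)
        assert x2[0] == pytest.approx(x1[0], abs=1e-9)

    def test_opposite_signs_flagged(self, geom, params):
        x, y, flags = tk.estimate_transversal(2.0, -2.0, geom, params)
        assert np.isnan(y[0])
        assert flags[0] & Flag.NO_INTERSECTION_TRANSVERSAL


class TestSegmentCorrection:
    def test_scales_displacement(self):
        p = tk.ModelParams(segment_ratio=0.85)
        assert tk.apply_segment_correction(-100.0, p) == pytest.approx(-85.0)

    def test_zero_is_fixed_point(self):
        for ratio in (0.5, 0.85, 1.0):
            assert tk.apply_segment_correction(0.0, tk.ModelParams(segment_ratio=ratio)) == 0.0

    def test_geometric_ratio_for_260mm_foot(self):
        ratio = tk.segment_ratio_from_foot_length(260.0, 1726.0)
        assert round(ratio, 2) == 0.85

    def test_x_not_modified_by_correction(self, geom):
        # the correction only touches the displacement channel
        p = tk.ModelParams(segment_ratio=0.85)
        x, z, _ = tk.estimate_sagittal(12.0, 7.0, geom, p)
        zc = tk.apply_segment_correction(z, p)
        assert zc[0] == pytest.approx(0.85 * z[0])
        x2, _, _ = tk.estimate_sagittal(12.0, 7.0, geom, tk.ModelParams(segment_ratio=1.0))
        assert x[0] == x2[0]


class TestPredictRoll:
    def test_ra_is_plain_sum(self, geom, params):
        out = tk.predict_roll(3.0, 2.0, None, geom, params, "RA")
        assert out[0] == pytest.approx(5.0)

    def test_zero_inputs_zero_output_all_variants(self, geom):
        p = tk.ModelParams(spring_coeff=2.0)
        for variant in ("RM", "RS", "RWS", "RA"):
            out = tk.predict_roll(0.0, 0.0, 0.0, geom, p, variant)
            assert out[0] == 0.0

    def test_rs_exact_on_simulator_scene(self, geom):
        k_true = 2.0
        load = tk.FootLoad(x_center=-200.0, depth=120.0, foot_roll=9.0)
        _, ang = tk.simulate_static(load, geom, spring_coeff=k_true)
        p = tk.ModelParams(spring_coeff=k_true)
        out = tk.predict_roll(ang.roll_front, ang.roll_back, -200.0, geom, p, "RS")
        assert out[0] == pytest.approx(9.0, abs=1e-6)
        out = tk.predict_roll(ang.roll_front, ang.roll_back, -200.0, geom, p, "RWS")
        assert out[0] == pytest.approx(9.0, abs=1e-6)

    def test_rm_equals_rs_at_unit_coefficient(self, geom):
        p = tk.ModelParams(spring_coeff=1.0)
        rm = tk.predict_roll(4.0, 2.0, 150.0, geom, p, "RM")
        rs = tk.predict_roll(4.0, 2.0, 150.0, geom, p, "RS")
        assert rm[0] == pytest.approx(rs[0])

    def test_uncalibrated_spring_coeff_warns(self, geom):
        with pytest.warns(UserWarning, match="uncalibrated"):
            tk.predict_roll(4.0, 2.0, 150.0, geom, tk.ModelParams(), "RS")

    def test_nan_position_propagates(self, geom):
        p = tk.ModelParams(spring_coeff=2.0)
        out = tk.predict_roll(4.0, 2.0, np.nan, geom, p, "RS")
        assert np.isnan(out[0])

    def test_position_outside_span_raises(self, geom):
        with pytest.raises(ValueError):
            tk.predict_roll(4.0, 2.0, 2000.0, geom, tk.ModelParams(spring_coeff=2.0), "RS")

    def test_unknown_variant_raises(self, geom, params):
        with pytest.raises(ValueError):
            tk.predict_roll(1.0, 1.0, 0.0, geom, params, "XX")


def _calibration_frames(rng, geom, *, n, ratio_true, k_true, noise_sigma, mode):
    """Synthetic single-mode manipulation frames with known parameters."""
    pairs = []
    for _ in range(n):
        if mode == "z_only":
            load = tk.FootLoad(
                x_center=rng.uniform(-350, 350),
                depth=rng.uniform(60, 300),
                flat_length=0.0,
            )
        else:
            load = tk.FootLoad(
                x_center=rng.uniform(-350, 350),
                depth=0.0,
                foot_roll=rng.uniform(5, 25) * rng.choice([-1, 1]),
            )
        shape, ang = tk.simulate_static(load, geom, spring_coeff=k_true)
        if mode == "z_only":
            # emulate the flat-foot depth reduction on the reference channel
            shape.polyline[:, 2] *= ratio_true
        for field in ("pitch_front", "pitch_back", "roll_front", "roll_back"):
            arr = getattr(ang, field)
            arr += rng.normal(0.0, noise_sigma, arr.shape)
        pairs.append((ang, shape))
    return pairs


class TestCalibrate:
    def test_recovers_segment_ratio(self, geom, rng):
        frames = _calibration_frames(
            rng, geom, n=200, ratio_true=0.85, k_true=2.0, noise_sigma=0.1, mode="z_only"
        )
        p = tk.calibrate(frames, ["segment_ratio"], geom)
        assert p.segment_ratio == pytest.approx(0.85, abs=0.01)

    def test_recovers_spring_coeff(self, geom, rng):
        frames = _calibration_frames(
            rng, geom, n=200, ratio_true=0.85, k_true=2.0, noise_sigma=0.1, mode="roll_only"
        )
        p = tk.calibrate(frames, ["spring_coeff"], geom)
        assert p.spring_coeff == pytest.approx(2.0, rel=0.05)

    def test_noiseless_frames_fit_exactly(self, geom, rng):
        frames = _calibration_frames(
            rng, geom, n=50, ratio_true=0.9, k_true=1.5, noise_sigma=0.0, mode="z_only"
        )
        p = tk.calibrate(frames, ["segment_ratio"], geom)
        assert p.segment_ratio == pytest.approx(0.9, abs=1e-9)

    def test_too_few_frames(self, geom, rng):
        frames = _calibration_frames(
            rng, geom, n=5, ratio_true=0.85, k_true=2.0, noise_sigma=0.0, mode="z_only"
        )
        with pytest.raises(CalibrationError):
            tk.calibrate(frames, ["segment_ratio"], geom)

    def test_degenerate_frames_raise(self, geom):
        pairs = []
        for _ in range(20):
            shape, ang = tk.simulate_static(tk.FootLoad(), tk.DeviceGeometry())
            pairs.append((ang, shape))
        with pytest.raises(CalibrationError):
            tk.calibrate(pairs, ["segment_ratio"], tk.DeviceGeometry())
        with pytest.raises(CalibrationError):
            tk.calibrate(pairs, ["spring_coeff"], tk.DeviceGeometry())

    def test_unknown_target(self, geom, rng):
        frames = _calibration_frames(
            rng, geom, n=20, ratio_true=0.85, k_true=2.0, noise_sigma=0.0, mode="z_only"
        )
        with pytest.raises(ValueError):
            tk.calibrate(frames, ["nope"], geom)


class TestQualityFlags:
    def _estimate(self, geom, pitch_back, pitch_front, yaw_back, yaw_front, times=None):
        n = len(pitch_back)
        ang = tk.AnchorAngles(
            time=times if times is not None else np.arange(n) / 200.0,
            pitch_back=pitch_back,
            pitch_front=pitch_front,
            yaw_back=yaw_back,
            yaw_front=yaw_front,
            roll_back=np.zeros(n),
            roll_front=np.zeros(n),
        )
        return tk.estimate_kinematics(ang, geom, tk.ModelParams(spring_coeff=1.0))

    def test_low_load(self, geom):
        est = self._estimate(geom, [0.01], [0.01], [0.01], [0.01])
        sets = tk.quality_flags(est, geom)
        assert "LOW_LOAD" in sets[0]

    def test_xz_xy_discrepancy(self, geom):
        # pitch pair symmetric (x=0); yaw pair strongly asymmetric (x far off)
        est = self._estimate(geom, [10.0], [10.0], [4.0], [1.0])
        assert abs(est.x_from_pitch[0] - est.x_from_yaw[0]) > 300
        sets = tk.quality_flags(est, geom, discrepancy_bound_mm=300.0)
        assert "XZ_XY_DISCREPANCY" in sets[0]

    def test_temporal_jump(self, geom):
        # two loaded frames with an X change of ~520 mm, no lift-off between
        est = self._estimate(geom, [10.0, 20.0], [10.0, 5.0], [1.0, 1.0], [1.0, 1.0])
        dx = abs(est.x_from_pitch[1] - est.x_from_pitch[0])
        assert dx > 300
        sets = tk.quality_flags(est, geom, foot_length_mm=300.0)
        assert "TEMPORAL_JUMP" in sets[1]

    def test_jump_allowed_after_lift_off(self, geom):
        est = self._estimate(
            geom,
            [10.0, 0.01, 20.0],
            [10.0, 0.01, 5.0],
            [1.0, 0.01, 1.0],
            [1.0, 0.01, 1.0],
        )
        sets = tk.quality_flags(est, geom, foot_length_mm=300.0)
        assert "TEMPORAL_JUMP" not in sets[2]
        assert "LOW_LOAD" in sets[1]


class TestRoundTrip:
    def test_point_load_recovery(self, geom, params, rng):
        for _ in range(100):
            x_true = rng.uniform(-700, 700)
            depth = rng.uniform(10, 350)
            _, ang = tk.simulate_static(tk.FootLoad(x_center=x_true, depth=depth), geom)
            x, z, flags = tk.estimate_sagittal(ang.pitch_back, ang.pitch_front, geom, params)
            assert flags[0] == 0
            assert x[0] == pytest.approx(x_true, abs=1e-6)
            assert z[0] == pytest.approx(-depth, abs=1e-6)

    def test_lateral_recovery(self, geom, params, rng):
        for _ in range(50):
            x_true = rng.uniform(-600, 600)
            y_true = rng.uniform(-60, 60)
            if abs(y_true) < 5:
                continue
            _, ang = tk.simulate_static(
                tk.FootLoad(x_center=x_true, depth=50.0, y_offset=y_true), geom
            )
            x, y, _ = tk.estimate_transversal(ang.yaw_back, ang.yaw_front, geom, params)
            assert x[0] == pytest.approx(x_true, abs=1e-6)
            assert y[0] == pytest.approx(y_true, abs=1e-6)
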