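"""Kinematics: limb angle conventions, event detection, cycle segmentation,
time-distance parameters, angle curves and RoMs, checked against the
generator's ground truth and analytic constructions."""

import numpy as np
import pytest

from gaitstage import kinematics as kin
from gaitstage.synthetic import FourierWaveform, default_gait_profile, generate_marker_walk


def _column(x, z, n=None):
    """F x 3 marker path from x/z coordinates (y = 0)."""
    x = np.broadcast_to(np.asarray(x, float), (n or np.size(x),))
    z = np.broadcast_to(np.asarray(z, float), x.shape)
    return np.column_stack([x, np.zeros_like(x), z])


class TestLimbAngle:
    def test_vertical_limb_is_zero(self):
        troch = _column([0.0, 0.0], [1.0, 1.0])
        mall = _column([0.0, 0.0], [0.1, 0.1])
        np.testing.assert_allclose(kin.limb_angle(troch, mall), 0.0, atol=1e-12)

    def test_equal_forward_and_downward_offset_is_45deg(self):
        troch = _column([0.0], [1.0])
        mall = _column([0.5], [0.5])
        assert kin.limb_angle(troch, mall)[0] == pytest.approx(45.0)

    def test_behind_vertical_is_negative(self):
        troch = _column([0.0], [1.0])
        mall = _column([-0.3], [0.2])
        assert kin.limb_angle(troch, mall)[0] < 0

    def test_coincident_markers_error_names_frame(self):
        troch = _column([0.0, 0.5], [1.0, 1.0])
        mall = _column([0.2, 0.5], [0.0, 1.0])
        with pytest.raises(ValueError, match="frame 1"):
            kin.limb_angle(troch, mall)

    def test_recovers_prescribed_waveform_on_synthetic_walk(self, clean_walk):
        mts, _ = clean_walk
        profile = default_gait_profile()
        t = np.arange(mts.n_frames) / mts.rate
        expected = profile.waveforms["limb_angle"](profile.cadence * t)
        got = kin.limb_angle(mts["l_trochanter"], mts["l_malleolus"])
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestEventDetection:
    def test_sine_wave_crest_spacing_equals_period(self):
        period = 120
        n = 5 * period
        s = 20 * np.sin(2 * np.pi * np.arange(n) / period)
        ev = kin.detect_gait_events(s, rate=100.0, smooth=False)
        assert np.all(np.diff(ev.heel_strikes) == period)
        # crests of sin at quarter-period offsets
        assert (ev.heel_strikes % period == period // 4).all()

    def test_constant_series_raises_insufficient_strides(self):
        with pytest.raises(kin.InsufficientStridesError):
            kin.detect_gait_events(np.ones(500), rate=100.0)

    def test_single_cycle_raises_insufficient_strides(self):
        s = 10 * np.sin(2 * np.pi * np.arange(120) / 100.0)
        with pytest.raises(kin.InsufficientStridesError):
            kin.detect_gait_events(s, rate=100.0, smooth=False)

    def test_detected_events_match_ground_truth_within_2_frames(self, clean_walk):
        mts, truth = clean_walk
        events = kin.detect_all_events(mts)
        for side in ("l", "r"):
            for det, gt in (
                (events[side].heel_strikes, truth.heel_strikes[side]),
                (events[side].toe_offs, truth.toe_offs[side]),
            ):
                assert len(det) >= len(gt) - 2
                err = np.abs(det[:, None] - gt[None, :]).min(axis=1)
                assert err.max() <= 2

    def test_alternation_enforced(self, noisy_walk):
        mts, _ = noisy_walk
        for side in ("l", "r"):
            ang = kin.limb_angle(mts[f"{side}_trochanter"], mts[f"{side}_malleolus"])
            ev = kin.detect_gait_events(ang, mts.rate)
            merged = sorted(
                [(f, "hs") for f in ev.heel_strikes] + [(f, "to") for f in ev.toe_offs]
            )
            kinds = [k for _, k in merged]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_uniform_progression_does_not_shift_events(self):
        # translation/uniform-speed invariance of the detector
        period = 150
        n = 6 * period
        s = 15 * np.sin(2 * np.pi * np.arange(n) / period) + 3.0
        a = kin.detect_gait_events(s, rate=100.0, smooth=False)
        b = kin.detect_gait_events(s + 5.0, rate=100.0, smooth=False)
        np.testing.assert_array_equal(a.heel_strikes, b.heel_strikes)


class TestCycles:
    def test_three_heel_strikes_give_two_cycles(self):
        ev = kin.GaitEvents(heel_strikes=[10, 110, 210], toe_offs=[70, 170])
        assert kin.segment_cycles(ev) == [(10, 110), (110, 210)]

    def test_single_heel_strike_gives_no_cycles(self):
        ev = kin.GaitEvents(heel_strikes=[10], toe_offs=[])
        assert kin.segment_cycles(ev) == []

    def test_generator_walk_yields_n_strides_minus_one_cycles(self, clean_walk):
        mts, _ = clean_walk
        events = kin.detect_all_events(mts)
        # 6 prescribed strides; boundary strides may be truncated
        for side in ("l", "r"):
            assert len(kin.segment_cycles(events[side])) >= 4


class TestTimeDistance:
    def test_speed_stance_swing_match_ground_truth(self):
        profile = default_gait_profile(speed=1.2, noise_sd=0.0)
        mts, truth = generate_marker_walk(profile, seed=0)
        feats = kin.extract_features(mts)
        assert feats["gait_speed"] == pytest.approx(1.2, abs=0.02)
        assert feats["stance_duration"] == pytest.approx(truth.stance_pct, rel=0.01)
        assert feats["swing_duration"] == pytest.approx(truth.swing_pct, rel=0.01)
        assert feats["cadence"] == pytest.approx(truth.cadence_steps, rel=0.01)

    def test_stance_swing_sum_to_100_exactly(self, clean_walk):
        mts, _ = clean_walk
        events = kin.detect_all_events(mts)
        per_stride, _ = kin.time_distance_params(mts, events, kin.limb_length(mts))
        total = per_stride["stance_duration"] + per_stride["swing_duration"]
        np.testing.assert_allclose(total.dropna(), 100.0, atol=1e-12)

    def test_symmetric_gait_has_equal_double_supports(self, clean_walk):
        mts, _ = clean_walk
        events = kin.detect_all_events(mts)
        _, mean = kin.time_distance_params(mts, events, kin.limb_length(mts))
        assert mean["double_support_1"] == pytest.approx(
            mean["double_support_2"], abs=0.5
        )

    def test_limb_length_is_mean_trochanter_malleolus_distance(self, clean_walk):
        mts, _ = clean_walk
        ll = kin.limb_length(mts, "l")
        profile = default_gait_profile()
        # chord of the two-segment leg, averaged over knee flexion
        assert profile.shank < ll <= profile.thigh + profile.shank

    def test_nonpositive_limb_length_rejected(self, clean_walk):
        mts, _ = clean_walk
        events = kin.detect_all_events(mts)
        with pytest.raises(ValueError, match="limb length"):
            kin.time_distance_params(mts, events, 0.0)


class TestJointAngles:
    def test_curves_have_101_samples(self, clean_walk):
        mts, _ = clean_walk
        events = kin.detect_all_events(mts)
        curves = kin.joint_angles(mts, events)
        for name, cycles in curves.items():
            assert cycles, name
            assert all(c.shape == (101,) for c in cycles)

    def test_static_pose_gives_constant_curves(self):
        profile = default_gait_profile(speed=0.4, noise_sd=0.0)
        for k in profile.waveforms:
            if k != "limb_angle":
                w = profile.waveforms[k]
                profile.waveforms[k] = FourierWaveform(w.mean, (), ())
        profile.waveforms["knee_flexion"] = FourierWaveform(20.0, (), ())
        mts, _ = generate_marker_walk(profile, seed=0)
        events = kin.detect_all_events(mts)
        curves = kin.joint_angles(mts, events)
        for name in ("knee", "trunk_rotation", "pelvis_tilt"):
            for c in curves[name]:
                assert np.ptp(c) < 1e-6, name

    def test_missing_marker_error_names_it(self, clean_walk):
        mts, _ = clean_walk
        events = kin.detect_all_events(mts)
        broken = kin.MarkerTrajectorySet(
            mts.rate, {k: v for k, v in mts.markers.items() if k != "c7"}
        )
        with pytest.raises(KeyError, match="c7"):
            kin.joint_angles(broken, events)

    def test_all_roms_recovered_within_1pct(self, clean_walk):
        mts, truth = clean_walk
        feats = kin.extract_features(mts)
        pairs = [
            ("hip", "rom_hip"), ("knee", "rom_knee"), ("ankle", "rom_ankle"),
            ("trunk_lateral_bending", "trunk_lateral_bending"),
            ("trunk_flexion_extension", "trunk_flexion_extension"),
            ("trunk_rotation", "trunk_rotation"),
            ("pelvis_obliquity", "pelvis_obliquity"),
            ("pelvis_rotation", "pelvis_rotation"),
            ("pelvis_tilt", "pelvis_tilt"),
        ]
        for gt_name, feat_name in pairs:
            assert feats[feat_name] == pytest.approx(
                truth.roms[gt_name], rel=0.01
            ), feat_name


class TestRom:
    def test_constant_curve_has_zero_rom(self):
        assert kin.rom(np.full(101, 12.3)) == 0.0

    def test_span_5_to_60_gives_55(self):
        assert kin.rom(np.linspace(5.0, 60.0, 101)) == pytest.approx(55.0)

    def test_rom_nonnegative_and_reversal_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.normal(size=101)
            r = kin.rom(c)
            assert r >= 0
            assert r == kin.rom(c[::-1])

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            kin.rom(np.array([]))


class TestMarkerCSV:
    def test_round_trip_preserves_rate_and_positions(self, tmp_path, noisy_walk):
        mts, _ = noisy_walk
        path = tmp_path / "trial.csv"
        mts.to_csv(path)
        assert path.read_text().startswith("# rate_hz=340")
        back = kin.MarkerTrajectorySet.from_csv(path)
        assert back.rate == mts.rate
        for name in mts.markers:
            np.testing.assert_allclose(back.markers[name], mts.markers[name], atol=1e-9)

    def test_nan_markers_rejected(self):
        arr = np.zeros((10, 3))
        arr[3, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            kin.MarkerTrajectorySet(100.0, {"c7": arr})
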