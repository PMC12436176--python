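"""Angle channels, smoothing, events, cycle normalization, classification."""

import numpy as np
import pytest

from conftest import random_rotation
from hffm.errors import NoCycleError, TrialRejectedError
from hffm.geometry import euler_xyz_compose
from hffm.kinematics import (
    CARDAN_BASIS,
    GaitCycleCurve,
    classify_foot_type,
    compute_angle_trajectories,
    compute_angles_frame,
    detect_gait_events,
    normalize_to_cycle,
    smooth_trajectories,
    summarize_curve,
)
from hffm.model import build_model
from hffm.synthetic import GaitWaveformConfig, generate_trial
from hffm.trial import GaitEvents, MarkerTrajectories


class TestAnglesFrame:
    def test_neutral_template_all_rigid_channels_zero(self, template_r):
        d = compute_angles_frame(template_r.neutral_frame()).as_dict()
        for name in (
            "hindfoot_shank_flexion", "hindfoot_shank_varus", "hindfoot_shank_rotation",
            "forefoot_hindfoot_flexion", "forefoot_hindfoot_supination",
            "forefoot_hindfoot_adduction", "forefoot_shank_flexion",
            "forefoot_shank_supination", "forefoot_shank_adduction",
            "hallux_flexion", "hallux_abduction",
        ):
            assert abs(d[name]) < 1e-9, name

    @pytest.mark.parametrize("angles", [(10, 0, 0), (0, 7, 0), (0, 0, -6), (8, -4, 3)])
    def test_prescribed_hindfoot_rotation_recovered(self, template_r, angles):
        # forward kinematics round trip: rotate the hindfoot+forefoot block
        # about the AJC and read the angles back
        m = template_r.neutral_frame()
        joints, poses = build_model(m)
        Q = poses.hindfoot.rotation @ CARDAN_BASIS
        A = Q @ euler_xyz_compose(angles) @ Q.T
        foot = {"LCL", "CCL", "MCL", "NAV", "DMT1", "PMT1", "DMT2", "DMT5",
                "PMT5", "HLX"}
        moved = {
            lbl: (A @ (p - joints.AJC) + joints.AJC if lbl in foot else p)
            for lbl, p in m.markers.items()
        }
        d = compute_angles_frame(type(m)(moved, side="R")).as_dict()
        assert d["hindfoot_shank_flexion"] == pytest.approx(angles[0], abs=1e-8)
        assert d["hindfoot_shank_varus"] == pytest.approx(angles[1], abs=1e-8)
        assert d["hindfoot_shank_rotation"] == pytest.approx(angles[2], abs=1e-8)
        # the forefoot moved with the hindfoot: no relative midfoot rotation
        assert abs(d["forefoot_hindfoot_flexion"]) < 1e-8

    def test_flat_arch_is_180(self):
        from hffm.model import MarkerFrame

        m = MarkerFrame({
            "MCL": [0, 0, 10], "NAV": [60, 0, 10], "DMT1": [150, 0, 10],
        })
        d = compute_angles_frame(m).as_dict()
        assert d["medial_arch"] == pytest.approx(180.0)
        assert np.isnan(d["hindfoot_shank_flexion"])  # missing markers only null channels

    def test_arch_decreases_as_navicular_rises(self, template_r):
        # cavus direction: higher navicular -> smaller apex angle
        arches = [
            compute_angles_frame(
                template_r.with_nav_raised(dz).neutral_frame()
            ).medial_arch
            for dz in (0.0, 5.0, 10.0, 15.0, 20.0)
        ]
        assert all(a > b for a, b in zip(arches, arches[1:]))

    def test_subtalar_eversion_sign(self, template_r):
        # rotate the hindfoot about the anterior axis so the lateral calcaneus
        # rises: that is eversion and must read positive on a right foot
        m = template_r.neutral_frame()
        a = np.radians(8.0)
        Rx = np.array([
            [1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]
        ])
        pivot = m["CCL"]
        moved = dict(m.markers)
        for lbl in ("MCL", "LCL", "CCL"):
            moved[lbl] = Rx @ (m[lbl] - pivot) + pivot
        lz_r = moved["LCL"][2] - moved["MCL"][2]
        d = compute_angles_frame(type(m)(moved, side="R")).as_dict()
        assert (lz_r > 0) == (d["subtalar_eversion"] > 0)
        assert abs(d["subtalar_eversion"]) == pytest.approx(8.0, abs=0.5)

    def test_rigid_invariance_all_channels(self, template_r, rng):
        m = template_r.neutral_frame()
        base = compute_angles_frame(m).as_dict()
        R = random_rotation(rng)
        t = rng.normal(scale=300, size=3)
        moved = compute_angles_frame(m.transformed(R, t)).as_dict()
        for name, v in base.items():
            assert moved[name] == pytest.approx(v, abs=1e-6), name


class TestSmoothing:
    def _traj(self, x, rate=100.0):
        n = len(x)
        data = {"CCL": np.column_stack([x, np.zeros(n), np.zeros(n)])}
        return MarkerTrajectories(data, rate=rate)

    def test_constant_preserved(self):
        out = smooth_trajectories(self._traj(np.full(200, 7.0)))
        assert np.allclose(out.data["CCL"][:, 0], 7.0, atol=1e-9)

    def test_gait_band_sine_passes_unchanged(self):
        t = np.arange(500) / 100.0
        x = 10.0 * np.sin(2 * np.pi * 1.0 * t)  # 1 Hz, well inside the passband
        out = smooth_trajectories(self._traj(x)).data["CCL"][:, 0]
        assert np.max(np.abs(out[50:-50] - x[50:-50])) < 0.01

    def test_spike_attenuated(self):
        x = np.zeros(400)
        x[200] = 10.0
        out = smooth_trajectories(self._traj(x)).data["CCL"][:, 0]
        # a single-sample 10 mm artifact is strongly attenuated by the
        # default 6 Hz-equivalent smoothing (about 6x)
        assert abs(out[200]) < 2.0

    def test_gap_interpolated_and_long_gap_rejected(self):
        t = np.arange(300) / 100.0
        x = np.sin(2 * np.pi * t)
        x_gap = x.copy()
        x_gap[100:105] = np.nan
        out = smooth_trajectories(self._traj(x_gap)).data["CCL"][:, 0]
        assert np.max(np.abs(out[100:105] - x[100:105])) < 0.05
        x_gap[100:150] = np.nan
        with pytest.raises(TrialRejectedError):
            smooth_trajectories(self._traj(x_gap))


class TestEvents:
    def test_detection_matches_generator_truth(self, noiseless_trial):
        traj, _, truth = noiseless_trial
        det = detect_gait_events(traj)
        assert len(det.initial_contact) == len(truth.initial_contact)
        assert np.max(np.abs(det.initial_contact - truth.initial_contact)) <= 2
        assert len(det.toe_off) == len(truth.toe_off)
        assert np.max(np.abs(det.toe_off - truth.toe_off)) <= 2

    def test_two_cycle_trial_yields_ordered_events(self, noiseless_trial):
        traj, _, _ = noiseless_trial
        det = detect_gait_events(traj)
        assert det.n_cycles == 2
        for k in range(det.n_cycles):
            assert det.initial_contact[k] < det.toe_off[k] < det.initial_contact[k + 1]

    def test_standing_trial_has_no_cycle(self, template_r):
        n = 300
        data = {k: np.tile(v, (n, 1)) for k, v in template_r.markers.items()}
        with pytest.raises(NoCycleError):
            detect_gait_events(MarkerTrajectories(data, rate=100.0))

    def test_noisy_detection_stays_close(self, template_r):
        cfg = GaitWaveformConfig(noise_sd_mm=1.0, n_cycles=5, seed=2)
        traj, _, truth = generate_trial(template_r, cfg)
        det = detect_gait_events(smooth_trajectories(traj))
        assert np.max(np.abs(det.initial_contact - truth.initial_contact)) <= 5
        assert np.max(np.abs(det.toe_off - truth.toe_off)) <= 5


def _events(ics):
    ics = np.asarray(ics)
    return GaitEvents(ics, (ics[:-1] + ics[1:]) // 2)


class TestCycleNormalization:
    def test_linear_ramp_preserved(self):
        series = np.arange(101.0)
        curve = normalize_to_cycle(series, _events([0, 100]))
        assert np.allclose(curve.values, np.arange(101.0), atol=1e-9)

    def test_identical_cycles_have_zero_sd(self):
        one = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        series = np.concatenate([one, one, one[:1]])
        curve = normalize_to_cycle(series, _events([0, 100, 200]))
        assert curve.n_cycles == 2
        assert np.max(curve.sd) < 1e-9

    def test_offset_cycles_average(self):
        # two cycles differing by a constant d average to base + d/2
        base = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        series = np.concatenate([base, base + 4.0, base[:1] + 4.0])
        curve = normalize_to_cycle(series, _events([0, 100, 200]))
        # interior points: mean = base + 2 (the boundary sample is shared by
        # both cycles, so only 1..99 are clean)
        assert np.allclose(curve.values[1:-1], base[1:100] + 2.0, atol=0.03)

    def test_incomplete_cycle_skipped(self):
        series = np.arange(150.0)
        curve = normalize_to_cycle(series, _events([0, 100, 200]))
        assert curve.n_cycles == 1


class TestSummary:
    def test_constant_curve(self):
        row = summarize_curve(GaitCycleCurve("x", np.full(101, 5.0)))
        assert (row.mean, row.max, row.rom) == (5.0, 5.0, 0.0)

    def test_sine_curve_closed_form(self):
        v = 10 * np.sin(np.linspace(0, 2 * np.pi, 101))
        row = summarize_curve(GaitCycleCurve("x", v))
        assert row.mean == pytest.approx(0.0, abs=0.1)
        assert row.max == pytest.approx(10.0, abs=0.05)
        assert row.rom == pytest.approx(20.0, abs=0.1)

    def test_rom_is_max_minus_min(self, rng):
        for _ in range(20):
            v = rng.normal(size=101)
            row = summarize_curve(GaitCycleCurve("x", v))
            assert row.rom == pytest.approx(v.max() - v.min())


class TestClassification:
    def test_rising_curve_is_ev(self):
        v = np.concatenate([np.linspace(0, 5, 6), np.full(95, 5.0)])
        label, slope = classify_foot_type(GaitCycleCurve("hf", v))
        assert label == "EV" and slope > 0

    def test_falling_curve_is_non_ev(self):
        v = np.concatenate([np.linspace(15, 10, 6), np.full(95, 10.0)])
        label, slope = classify_foot_type(GaitCycleCurve("hf", v))
        assert label == "non-EV" and slope < 0

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            classify_foot_type(GaitCycleCurve("hf", np.zeros(101)), window_percent=0.5)


class TestTrajectoryPipeline:
    def test_noiseless_round_trip(self, template_r, noiseless_trial):
        traj, truth, _ = noiseless_trial
        rec = compute_angle_trajectories(
            traj, calibration=template_r.neutral_frame(), smooth=False
        )
        for name, expected in truth.items():
            assert np.nanmax(np.abs(rec[name] - expected)) < 0.5, name

    def test_global_rigid_transform_changes_no_angle(self, template_r,
                                                     noiseless_trial, rng):
        traj, _, _ = noiseless_trial
        cal = template_r.neutral_frame()
        base = compute_angle_trajectories(traj, cal, smooth=False)
        R = random_rotation(rng)
        t = rng.normal(scale=1000, size=3)
        moved = compute_angle_trajectories(
            traj.transformed(R, t), cal.transformed(R, t), smooth=False
        )
        for name in base:
            assert np.nanmax(np.abs(base[name] - moved[name])) < 1e-6, name

    def test_mirrored_left_trial_equals_right(self, template_r, noiseless_trial):
        traj, _, _ = noiseless_trial
        base = compute_angle_trajectories(
            traj, template_r.neutral_frame(), smooth=False
        )
        M = np.diag([1.0, -1.0, 1.0])
        mirrored = MarkerTrajectories(
            {k: v @ M for k, v in traj.data.items()}, rate=traj.rate, side="L"
        )
        cal = template_r.neutral_frame().transformed(M, np.zeros(3))
        cal.side = "L"
        rec = compute_angle_trajectories(mirrored, cal, smooth=False)
        for name in base:
            assert np.nanmax(np.abs(base[name] - rec[name])) < 1e-6, name
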