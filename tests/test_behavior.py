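"""Behavior rules on constructed tracks and planted synthetic sessions."""

import numpy as np
import pytest

from pagstates import behavior as bhv
from pagstates.core import AssayGeometry, AssayKind, BehaviorIntervals

FPS = 30.0


def _stationary(n, xy0=(20.0, 13.0)):
    return np.tile(np.asarray(xy0, float), (n, 1))


def _line(n, start, step):
    return np.asarray(start, float) + np.arange(n)[:, None] * np.asarray(step, float)


class TestKinematics:
    def test_stationary_track_zero_speed(self, make_pose):
        pose = make_pose(_stationary(120), AssayGeometry.rat(), rat_xy=(66.0, 13.0))
        kin = bhv.compute_kinematics(pose)
        np.testing.assert_allclose(kin.speed_body, 0.0, atol=1e-12)

    def test_straight_line_speed(self, make_pose):
        # 1 cm per frame at 30 fps -> 30 cm/s
        pose = make_pose(_line(200, (5.0, 13.0), (1.0 / 30 * 30, 0)), AssayGeometry.rat(),
                         rat_xy=(66.0, 13.0))
        pose = make_pose(_line(200, (5.0, 13.0), (1.0, 0.0)), AssayGeometry.rat(),
                         rat_xy=(200.0, 13.0))
        kin = bhv.compute_kinematics(pose)
        np.testing.assert_allclose(kin.speed_body[10:-10], 30.0, atol=1e-9)

    def test_circular_path_constant_speed_zero_radial(self, make_pose):
        """On a circle around the threat, speed is constant and the radial
        velocity to the center is identically zero (analytic circle)."""
        t = np.arange(600) / FPS
        r, omega = 8.0, 1.2  # rad/s -> speed = r*omega = 9.6 cm/s
        center = np.array([40.0, 13.0])
        xy = center + r * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        pose = make_pose(xy, AssayGeometry.rat(), rat_xy=center)
        kin = bhv.compute_kinematics(pose)
        np.testing.assert_allclose(kin.speed_body[10:-10], r * omega, rtol=1e-3)
        np.testing.assert_allclose(kin.radial_velocity[10:-10], 0.0, atol=1e-6)

    def test_fewer_than_two_frames_rejected(self, make_pose):
        pose = make_pose(_stationary(1), AssayGeometry.epm())
        with pytest.raises(ValueError, match="2 frames"):
            bhv.compute_kinematics(pose)

    def test_detectors_invariant_to_translation(self, make_pose, rat_session):
        kin_a = bhv.compute_kinematics(rat_session.pose)
        kin_b = bhv.compute_kinematics(rat_session.pose.translated(3.0, -2.0))
        a = bhv.detect_freeze(kin_a).table
        b = bhv.detect_freeze(kin_b).table
        np.testing.assert_allclose(a["onset_s"], b["onset_s"])
        a2 = bhv.detect_approach_escape(kin_a).table
        b2 = bhv.detect_approach_escape(kin_b).table
        np.testing.assert_allclose(a2["onset_s"], b2["onset_s"])


class TestFreeze:
    def _pose_with_still_block(self, make_pose, still_frames, slow_tail=False):
        n = 600
        xy = _line(n, (10.0, 13.0), (1.5 / FPS, 0.0))  # 1.5 cm/s walk
        a = 300
        xy[a:a + still_frames] = xy[a]
        xy[a + still_frames:] = (xy[a] + np.arange(n - a - still_frames)[:, None]
                                 * np.array([1.5 / FPS, 0.0]))
        return make_pose(xy, AssayGeometry.rat(), rat_xy=(66.0, 13.0))

    def test_short_stillness_is_not_freeze(self, make_pose):
        # 0.2 s below threshold: shorter than the 0.33 s minimum
        pose = self._pose_with_still_block(make_pose, int(0.2 * FPS))
        kin = bhv.compute_kinematics(pose)
        assert len(bhv.detect_freeze(kin)) == 0

    def test_one_second_stillness_recovered_within_one_frame(self, make_pose):
        pose = self._pose_with_still_block(make_pose, int(1.0 * FPS))
        kin = bhv.compute_kinematics(pose)
        det = bhv.detect_freeze(kin)
        assert len(det) == 1
        assert abs(det.table["onset_s"][0] - 300 / FPS) <= 1.01 / FPS

    def test_conjunction_both_keypoints_required(self):
        """Head slow but tailbase above threshold: no freeze."""
        n = 300
        g = AssayGeometry.rat()
        still = np.tile([20.0, 13.0], (n, 1))
        tail = _line(n, (17.0, 13.0), (0.3 / FPS, 0.0))  # 0.3 cm/s > 0.25
        from pagstates.core import PoseTrack
        kp = {"nose": still.copy(), "ear_l": still.copy(), "ear_r": still.copy(),
              "tailbase": tail, "rat": np.tile([66.0, 13.0], (n, 1))}
        kin = bhv.compute_kinematics(PoseTrack(kp, FPS, g))
        assert len(bhv.detect_freeze(kin)) == 0


class TestApproachEscape:
    def test_epm_input_rejected(self, make_pose):
        pose = make_pose(_stationary(100, (0.0, 0.0)), AssayGeometry.epm())
        kin = bhv.compute_kinematics(pose)
        with pytest.raises(ValueError, match="rat"):
            bhv.detect_approach_escape(kin)

    def test_run_toward_rat_at_5cms_is_single_approach(self, make_pose):
        xy = _line(450, (20.0, 13.0), (5.0 / FPS, 0.0))
        pose = make_pose(xy, AssayGeometry.rat(), rat_xy=(200.0, 13.0))
        det = bhv.detect_approach_escape(bhv.compute_kinematics(pose))
        assert len(det.of("approach")) == 1
        assert len(det.of("escape")) == 0

    def test_subthreshold_speed_not_detected(self, make_pose):
        # 2 cm/s toward the rat: below the 3 cm/s threshold
        xy = _line(450, (20.0, 13.0), (2.0 / FPS, 0.0))
        pose = make_pose(xy, AssayGeometry.rat(), rat_xy=(200.0, 13.0))
        det = bhv.detect_approach_escape(bhv.compute_kinematics(pose))
        assert len(det) == 0

    def test_run_away_is_escape(self, make_pose):
        xy = _line(450, (50.0, 13.0), (-5.0 / FPS, 0.0))
        pose = make_pose(xy, AssayGeometry.rat(), rat_xy=(200.0, 13.0))
        det = bhv.detect_approach_escape(bhv.compute_kinematics(pose))
        assert len(det.of("escape")) == 1
        assert len(det.of("approach")) == 0


class TestRatMovements:
    def _rat_track(self, bursts, n=9000, direction=(1.0, 0.0)):
        rat = np.tile([60.0, 13.0], (n, 1)).astype(float)
        for onset, dur in bursts:
            for k in range(dur):
                rat[onset + k] = rat[onset + k - 1] + (10.0 - 0.01 * k) / FPS * np.asarray(direction)
            rat[onset + dur:] = rat[onset + dur - 1]
        return rat

    def test_two_bursts_within_merge_window_keep_first(self, make_pose):
        bursts = [(3000, 60), (3000 + int(3.0 * FPS), 60)]  # 3 s apart < 5.33 s
        rat = self._rat_track(bursts)
        pose = make_pose(_line(9000, (10.0, 5.0), (0.02, 0.0))[:9000] * 0 + [10.0, 5.0],
                         AssayGeometry.rat(), rat_xy=rat)
        det = bhv.detect_rat_movements(bhv.compute_kinematics(pose))
        assert len(det) == 1
        assert abs(det.table["onset_s"][0] - 3000 / FPS) <= 1.5 / FPS

    def test_stationary_rat_no_events(self, make_pose):
        pose = make_pose(_stationary(600, (10.0, 5.0)), AssayGeometry.rat(),
                         rat_xy=(60.0, 13.0))
        det = bhv.detect_rat_movements(bhv.compute_kinematics(pose))
        assert len(det) == 0

    def test_burst_straight_at_mouse_has_zero_angle(self, make_pose):
        mouse = np.tile([10.0, 13.0], (9000, 1)).astype(float)
        rat = self._rat_track([(4000, 60)], direction=(-1.0, 0.0))  # toward the mouse
        pose = make_pose(mouse, AssayGeometry.rat(), rat_xy=rat)
        det = bhv.detect_rat_movements(bhv.compute_kinematics(pose))
        assert len(det) == 1
        ang = det.table["meta"][0]["angle_deg"]
        assert min(ang, 360 - ang) < 5.0


class TestHeadDips:
    def test_nose_inside_arm_no_dip(self, epm_session):
        zones = bhv.assign_zones(epm_session.pose, epm_session.geometry)
        pose = epm_session.pose
        # clamp the nose inside the arm: no dips anywhere
        import copy
        kp = {k: v.copy() for k, v in pose.keypoints.items()}
        kp["nose"][:, 1] = np.clip(kp["nose"][:, 1], -3.0, 3.0)
        from pagstates.core import PoseTrack
        clamped = PoseTrack(kp, pose.fps, pose.geometry)
        assert len(bhv.detect_head_dips(clamped, zones)) == 0

    def test_dip_geometry_in_closed_arm_is_not_a_dip(self, make_pose):
        """Nose past a lateral boundary while the body sits in a closed arm:
        the rule conjunction (body in open arm) fails."""
        n = 300
        g = AssayGeometry.epm()
        body = np.tile([0.0, 20.0], (n, 1)).astype(float)  # closed arm (+y)
        from pagstates.core import PoseTrack
        kp = {k: body.copy() for k in ("ear_l", "ear_r", "tailbase")}
        nose = body.copy()
        nose[:, 0] = 5.0  # past the lateral boundary of the closed arm
        kp["nose"] = nose
        pose = PoseTrack(kp, FPS, g)
        zones = bhv.assign_zones(pose, g)
        assert len(bhv.detect_head_dips(pose, zones)) == 0

    def test_requires_epm(self, make_pose):
        pose = make_pose(_stationary(100), AssayGeometry.rat(), rat_xy=(66.0, 13.0))
        zones = bhv.assign_zones(pose, pose.geometry)
        with pytest.raises(ValueError, match="EPM"):
            bhv.detect_head_dips(pose, zones)


class TestZones:
    def test_rat_zone_rules(self, make_pose):
        g = AssayGeometry.rat()
        rat = np.array([66.0, 13.0])
        pts = np.array([
            [0.1 * g.arena_length, 13.0],  # left 20% -> safe
            [66.0 - 14.0, 13.0],           # exactly 14 cm away -> threatening
            [30.0, 13.0],                  # neither -> middle
        ])
        pose = make_pose(pts, g, rat_xy=rat)
        zones = bhv.assign_zones(pose, g)
        assert list(zones.labels) == ["safe", "threatening", "middle"]

    def test_epm_labels(self, make_pose):
        g = AssayGeometry.epm()
        pts = np.array([
            [0.0, 0.0],     # center
            [20.0, 0.0],    # open1
            [-20.0, 0.0],   # open2
            [0.0, 20.0],    # closed1
            [0.0, -20.0],   # closed2
        ])
        zones = bhv.assign_zones(make_pose(pts, g), g)
        assert list(zones.labels) == ["center", "open1", "open2", "closed1", "closed2"]
        assert zones.is_open.sum() == 2 and zones.is_closed.sum() == 2

    def test_point_far_outside_raises(self, make_pose):
        g = AssayGeometry.epm()
        with pytest.raises(ValueError, match="outside"):
            bhv.assign_zones(make_pose(np.array([[80.0, 0.0]]), g), g)

    def test_exactly_one_label_per_frame(self, epm_prepared):
        zones = epm_prepared.zones
        assert (zones.is_open.astype(int) + zones.is_closed.astype(int)
                + zones.is_center.astype(int)).max() == 1
        assert len(zones.labels) == epm_prepared.session.pose.n_frames


class TestLocationIndex:
    @pytest.mark.parametrize("xy,expected", [
        ((33.5, 0.0), 1.0),    # open-arm end
        ((0.0, 0.0), 0.0),     # center
        ((0.0, 33.5), -1.0),   # closed-arm end
        ((0.5 * 33.5, 0.3 * 33.5), 0.2),
    ])
    def test_reference_points(self, make_pose, xy, expected):
        g = AssayGeometry.epm()
        pose = make_pose(np.array([xy]), g)
        idx = bhv.epm_location_index(pose, g)
        assert idx[0] == pytest.approx(expected, abs=1e-9)

    def test_mirror_symmetry(self, epm_session):
        """Reflecting the maze across the center leaves |index| unchanged."""
        g = epm_session.geometry
        pose = epm_session.pose
        from pagstates.core import PoseTrack
        mirrored = PoseTrack({k: -v for k, v in pose.keypoints.items()}, pose.fps, g)
        a = bhv.epm_location_index(pose, g)
        b = bhv.epm_location_index(mirrored, g)
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-12)
        za = bhv.assign_zones(pose, g).labels
        zb = bhv.assign_zones(mirrored, g).labels
        swap = {"open1": "open2", "open2": "open1",
                "closed1": "closed2", "closed2": "closed1", "center": "center"}
        assert all(zb[i] == swap[za[i]] for i in range(len(za)))


class TestAvoidanceApproachScore:
    def test_freeze_frames_forced_to_minimum(self, make_pose):
        xy = _line(300, (20.0, 13.0), (2.0 / FPS, 0.0))
        pose = make_pose(xy, AssayGeometry.rat(), rat_xy=(66.0, 13.0))
        iv = BehaviorIntervals.from_records([("freeze", 3.0, 5.0)])
        s = bhv.avoidance_approach_score(pose, iv, pose.geometry)
        frames = slice(int(3.0 * FPS), int(5.0 * FPS))
        np.testing.assert_array_equal(s.score[frames], -1.0)

    def test_adjacent_to_rat_while_approaching_is_plus_one(self, make_pose):
        """A straight approach from the safe wall to the rat: the terminal
        toward-threat frame carries the maximum score of +1."""
        xy = _line(600, (2.0, 13.0), (3.2 / FPS, 0.0))
        pose = make_pose(xy, AssayGeometry.rat(), rat_xy=(66.0, 13.0))
        s = bhv.avoidance_approach_score(pose, BehaviorIntervals(), pose.geometry)
        assert s.direction[-1] == 1.0
        assert s.score[-1] == pytest.approx(1.0, abs=1e-9)

    def test_head_dip_at_open_arm_end_reaches_one(self, make_pose):
        """EPM head dip at the open-arm end: 0.9 x 1.11 = 0.999, i.e. 1.00
        after rounding to two decimals."""
        g = AssayGeometry.epm()
        # walk from the closed-arm end through the center to the open-arm end
        leg1 = _line(335, (0.0, 33.5), (0.0, -0.1))
        leg2 = _line(336, (0.0, 0.0), (0.1, 0.0))
        xy = np.vstack([leg1, leg2])
        pose = make_pose(xy, g)
        n = len(xy)
        dip = BehaviorIntervals.from_records([("head_dip", (n - 10) / FPS, n / FPS)])
        s = bhv.avoidance_approach_score(pose, dip, g)
        assert s.score[-1] == pytest.approx(0.9 * 1.11, abs=1e-6)
        assert round(float(s.score[-1]), 2) == 1.0

    def test_away_at_closed_end_is_minus_one(self, make_pose):
        g = AssayGeometry.epm()
        # retreat from the open arm end to the closed arm end
        leg1 = _line(335, (33.5, 0.0), (-0.1, 0.0))
        leg2 = _line(336, (0.0, 0.0), (0.0, 0.1))
        pose = make_pose(np.vstack([leg1, leg2]), g)
        s = bhv.avoidance_approach_score(pose, BehaviorIntervals(), g)
        assert s.direction[-1] == -1.0
        assert s.score[-1] == pytest.approx(-1.0, abs=1e-9)

    def test_score_bounds_on_synthetic_sessions(self, epm_prepared, rat_prepared):
        for p in (epm_prepared, rat_prepared):
            assert p.scores.score.min() >= -1.0 - 1e-12
            assert p.scores.score.max() <= 1.0 + 1e-12
            if p.scores.location_index is not None:
                assert np.abs(p.scores.location_index).max() <= 1.0 + 1e-12


class TestPlantedRecovery:
    def test_all_planted_events_recovered_one_frame(self, epm_session, rat_session):
        """Every planted event class is recovered with onset error <= 1 frame
        and matching counts under noiseless kinematics."""
        for sess in (epm_session, rat_session):
            pose, truth = sess.pose, sess.truth
            kin = bhv.compute_kinematics(pose)
            det = bhv.detect_freeze(kin)
            if sess.geometry.is_epm:
                det = det + bhv.detect_head_dips(pose, bhv.assign_zones(pose, sess.geometry))
            else:
                det = det + bhv.detect_approach_escape(kin) + bhv.detect_rat_movements(kin)
            for label in sorted(truth.events.labels()):
                planted = truth.events.of(label)["onset_s"].to_numpy()
                found = det.of(label)["onset_s"].to_numpy()
                assert len(found) == len(planted), (label, len(found), len(planted))
                err = max(np.min(np.abs(found - p)) for p in planted) * pose.fps
                assert err <= 1.01, (label, err)
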