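import numpy as np
import pytest

from arlabels.errors import EmptyClockError
from arlabels.geometry import RigidTransform, compose, interpolate_pose, invert
from arlabels.replay import (
    Replayer,
    resample_stream,
    resolve_scene,
    resolve_transform,
)
from arlabels.session import FrameClock, TransformStream


def make_stream(times, valid=None, rng=None, name="s", parent="tracker", child="array"):
    rng = rng if rng is not None else np.random.default_rng(0)
    n = len(times)
    qs = rng.normal(size=(n, 4))
    qs /= np.linalg.norm(qs, axis=1, keepdims=True)
    ts = rng.normal(size=(n, 3)) * 30
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return TransformStream(name, parent, child, np.asarray(times, float), qs, ts, valid)


class TestResampleStream:
    def test_native_timestamps_exact(self):
        times = np.arange(0, 60) / 60.0
        stream = make_stream(times)
        out = resample_stream(stream, FrameClock(times, 60))
        assert all(r.source == "exact" and r.valid for r in out)
        for i, r in enumerate(out):
            assert np.array_equal(r.pose.quaternion, stream.pose(i).quaternion)
            assert np.array_equal(r.pose.translation, stream.translations[i])

    def test_dropout_gap_invalid(self):
        # 1.0 s dropout with max_gap 0.2 s
        times = np.concatenate([np.arange(0, 0.5, 1 / 60), np.arange(1.5, 2.0, 1 / 60)])
        stream = make_stream(times)
        out = resample_stream(stream, FrameClock(np.array([1.0]), 30), max_gap=0.2)
        assert not out[0].valid and out[0].source == "gap"

    def test_midpoint_matches_interpolate_oracle(self):
        times = np.array([0.0, 1 / 60])
        stream = make_stream(times)
        mid = times.mean()
        out = resample_stream(stream, FrameClock(np.array([mid]), 30))
        expected = interpolate_pose(0.0, stream.pose(0), 1 / 60, stream.pose(1), mid)
        assert out[0].valid and out[0].pose.isclose(expected, atol=1e-12)

    def test_invalid_samples_skipped(self):
        times = np.arange(5) / 60.0
        valid = np.array([True, False, True, True, True])
        stream = make_stream(times, valid)
        t = (times[0] + times[2]) / 2  # bracketed by valid 0 and 2
        out = resample_stream(stream, FrameClock(np.array([t]), 30), max_gap=0.2)
        expected = interpolate_pose(times[0], stream.pose(0), times[2], stream.pose(2), t)
        assert out[0].pose.isclose(expected, atol=1e-12)

    def test_clamp_only_within_half_median_interval(self):
        times = np.arange(10) / 60.0
        stream = make_stream(times)
        clock = FrameClock(np.array([times[-1] + 0.004, times[-1] + 0.1]), 30)
        out = resample_stream(stream, clock)
        assert out[0].valid  # within half the 1/60 s median interval
        assert not out[1].valid

    def test_empty_clock(self):
        stream = make_stream(np.arange(3) / 60.0)
        with pytest.raises(EmptyClockError):
            resample_stream(stream, FrameClock(np.array([]), 30))

    def test_max_gap_positive(self):
        stream = make_stream(np.arange(3) / 60.0)
        with pytest.raises(ValueError):
            resample_stream(stream, FrameClock(np.array([0.0]), 30), max_gap=0.0)


class TestResolveTransform:
    def test_same_frame_identity(self, small_session):
        session, _ = small_session
        pose, valid = resolve_transform(session, "patient", "patient", 1.0)
        assert valid and pose.isclose(RigidTransform.identity())

    def test_matches_manual_composition(self, small_session):
        session, _ = small_session
        t = 1.0
        # tracker -> grasper_array (dynamic) composed with the static tip offset
        pose, valid = resolve_transform(session, "tracker", "grasper_array", t)
        assert valid
        stream = next(s for s in session.streams if s.name == "grasper")
        i = int(np.searchsorted(stream.times, t))
        assert abs(stream.times[i] - t) < 1e-9
        assert pose.isclose(stream.pose(i), atol=1e-12)

    def test_antisymmetry(self, small_session):
        session, _ = small_session
        for t in (0.5, 2.0, 7.5):
            ab, v1 = resolve_transform(session, "camera", "patient", t)
            ba, v2 = resolve_transform(session, "patient", "camera", t)
            assert v1 and v2
            assert compose(ab, ba).isclose(RigidTransform.identity(), atol=1e-9)

    def test_unknown_and_disconnected(self, small_session):
        session, _ = small_session
        from arlabels.errors import UnknownFrameError

        with pytest.raises(UnknownFrameError):
            resolve_transform(session, "patient", "ghost", 0.0)

    def test_gap_propagates_invalid(self, small_session):
        from dataclasses import replace

        session, _ = small_session
        stream = next(s for s in session.streams if s.name == "scope")
        valid = stream.valid.copy()
        valid[(stream.times >= 3.0) & (stream.times <= 4.0)] = False
        patched = replace(
            session,
            streams=[
                s if s.name != "scope"
                else TransformStream(s.name, s.parent_frame, s.child_frame, s.times,
                                     s.quaternions, s.translations, valid)
                for s in session.streams
            ],
        )
        pose, ok = resolve_transform(patched, "camera", "patient", 3.5)
        assert not ok and pose is None
        # monotone validity: instrument chain unaffected
        _, ok2 = resolve_transform(patched, "patient", "grasper_array", 3.5)
        assert ok2

    def test_validity_monotone_under_dropout(self, small_session):
        """A dropout can only invalidate results, never change a valid pose."""
        from dataclasses import replace

        session, _ = small_session
        t = 5.0
        before, ok = resolve_transform(session, "camera", "grasper_array", t)
        assert ok
        stream = next(s for s in session.streams if s.name == "table")
        valid = stream.valid.copy()
        valid[:] = True
        valid[(stream.times > 4.5) & (stream.times < 5.5)] = False
        patched = replace(
            session,
            streams=[
                s if s.name != "table"
                else TransformStream(s.name, s.parent_frame, s.child_frame, s.times,
                                     s.quaternions, s.translations, valid)
                for s in session.streams
            ],
        )
        # camera->grasper path crosses the table edge twice (up and down): invalid
        after, ok2 = resolve_transform(patched, "patient", "grasper_array", t)
        assert not ok2
        # a path not using the table edge keeps its exact pose
        same, ok3 = resolve_transform(patched, "tracker", "grasper_array", t)
        ref, _ = resolve_transform(session, "tracker", "grasper_array", t)
        assert ok3 and same.isclose(ref, atol=1e-15)


class TestResolveScene:
    def test_all_valid(self, small_session):
        session, _ = small_session
        scene = resolve_scene(session, 1.0)
        assert scene.root_frame == "patient"
        assert scene.poses["patient"][0].isclose(RigidTransform.identity())
        assert all(valid for _, valid in scene.poses.values())
        assert "grasper_tip" in scene.poses and "camera" in scene.poses

    def test_camera_root_algebraic_oracle(self, small_session):
        session, _ = small_session
        t = 2.0
        scene_p = resolve_scene(session, t, root_frame="patient")
        scene_c = resolve_scene(session, t, root_frame="camera")
        cam_in_patient = scene_p.poses["camera"][0]
        anat_frame = session.anatomies[0].frame
        anat_in_cam = scene_c.poses[anat_frame][0]
        expected = compose(invert(cam_in_patient), scene_p.poses[anat_frame][0])
        assert anat_in_cam.isclose(expected, atol=1e-9)

    def test_camera_dropout_keeps_instruments(self, small_session):
        from dataclasses import replace

        session, _ = small_session
        stream = next(s for s in session.streams if s.name == "scope")
        valid = np.zeros_like(stream.valid)
        patched = replace(
            session,
            streams=[
                s if s.name != "scope"
                else TransformStream(s.name, s.parent_frame, s.child_frame, s.times,
                                     s.quaternions, s.translations, valid)
                for s in session.streams
            ],
        )
        scene = resolve_scene(patched, 1.0)
        assert not scene.poses["camera"][1]
        assert scene.poses["grasper_tip"][1]


class TestReplayer:
    def test_matches_resolve_transform(self, small_session):
        session, _ = small_session
        rep = Replayer(session)
        for fi in (0, 17, 100):
            t = float(session.clock.times[fi])
            a, ok_a = rep.resolve_at_frame(fi, "camera", "grasper_array")
            b, ok_b = resolve_transform(session, "camera", "grasper_array", t)
            assert ok_a == ok_b
            assert a.isclose(b, atol=1e-12)

    def test_tip_position(self, small_session):
        session, truth = small_session
        rep = Replayer(session)
        inst = session.instruments[0]
        fi = 60
        tip, ok = rep.tip_position_at_frame(fi, inst)
        assert ok
        expected = truth.tip_paths[inst.name](float(session.clock.times[fi]))
        assert np.abs(tip - expected).max() < 1e-6
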