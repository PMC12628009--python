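import numpy as np
import pytest

from arlabels.errors import ConfigurationError
from arlabels.events import (
    DistanceRecord,
    Kinematics,
    RuleConfig,
    TripletEvent,
    aggregate_triplets,
    compute_distance_series,
    compute_kinematics,
    infer_frame_state,
    infer_session_triplets,
    score_events,
)
from arlabels.session import FrameClock
from arlabels.synth import (
    AnatomySpec,
    ContactSpec,
    InstrumentScript,
    SynthConfig,
    generate_session,
)


def clock_30fps(n):
    return FrameClock(np.arange(n) / 30.0, nominal_rate=30.0)


# ---------------------------------------------------------------------------
# distance series
# ---------------------------------------------------------------------------

def flyby_config(clearance=2.0):
    scene = (AnatomySpec(name="target", shape="sphere", size=(20.0,), center=(0.0, 0.0, 0.0), label_id=1),)
    inst = InstrumentScript(
        name="probe",
        archetype="grasper",
        rest_position=(60.0, 30.0, 20.0),
        contacts=(ContactSpec("target", t_start=2.0, dwell=1.5, clearance=clearance),),
    )
    return SynthConfig(duration=6.0, scene=scene, instruments=(inst,), seed=4)


class TestComputeDistanceSeries:
    def test_scripted_flyby_minimum(self):
        session, truth = generate_session(flyby_config(clearance=2.0))
        records = compute_distance_series(session)
        dmin = min(r.distance for r in records if r.valid)
        tol = truth.chord_tolerances["target"]
        assert 2.0 - 1e-6 <= dmin <= 2.0 + tol + 1e-6

    def test_dropout_marks_invalid(self):
        from dataclasses import replace

        from arlabels.session import TransformStream

        session, _ = generate_session(flyby_config())
        stream = next(s for s in session.streams if s.name == "probe")
        valid = stream.valid.copy()
        valid[(stream.times >= 1.0) & (stream.times <= 1.6)] = False
        patched = replace(
            session,
            streams=[
                s if s.name != "probe"
                else TransformStream(s.name, s.parent_frame, s.child_frame, s.times,
                                     s.quaternions, s.translations, valid)
                for s in session.streams
            ],
        )
        records = compute_distance_series(patched)
        bad = [r for r in records if 1.1 < r.t < 1.5 and r.instrument == "probe"]
        assert bad and all(not r.valid for r in bad)

    def test_off_screen_contact_still_recorded(self, demo_pipeline):
        session, truth, records, _, _, events = demo_pipeline
        # the grasper-mesentery contact happens fully outside the frustum
        dwell = [r for r in records
                 if r.instrument == "grasper" and r.structure == "mesentery" and 20.5 < r.t < 22.5]
        assert dwell and all(r.valid for r in dwell)
        assert max(r.distance for r in dwell) < 3.0
        assert any(e.target == "mesentery" and e.instrument == "grasper" for e in events)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

class TestComputeKinematics:
    def test_constant_velocity(self):
        clock = clock_30fps(90)
        pos = np.outer(clock.times, [10.0, 0.0, 0.0])  # 10 mm/s along x
        kin = compute_kinematics(pos, clock, window=5, instrument="i")
        interior = [k.speed for k in kin[5:-5]]
        assert np.allclose(interior, 10.0, atol=1e-6)

    def test_stationary(self):
        clock = clock_30fps(60)
        pos = np.tile([5.0, 5.0, 5.0], (60, 1))
        kin = compute_kinematics(pos, clock, window=5, nearest_distances=np.full(60, 4.0))
        assert all(k.speed == 0.0 and k.approach_rate == 0.0 for k in kin)

    def test_smooth_trajectory_matches_dense_oracle(self):
        clock = clock_30fps(150)
        t = clock.times
        pos = np.stack([20 * np.sin(0.8 * t), 12 * np.cos(0.5 * t), 3 * t], axis=1)
        kin = compute_kinematics(pos, clock, window=5)
        # dense finite-difference oracle on a 100x finer grid
        tf = np.linspace(t[0], t[-1], len(t) * 100)
        pf = np.stack([20 * np.sin(0.8 * tf), 12 * np.cos(0.5 * tf), 3 * tf], axis=1)
        vf = np.gradient(pf, tf, axis=0)
        speed_f = np.interp(t, tf, np.linalg.norm(vf, axis=1))
        got = np.array([k.speed for k in kin])
        rel = np.abs(got[3:-3] - speed_f[3:-3]) / np.maximum(speed_f[3:-3], 1e-9)
        assert rel.max() < 0.02

    def test_invalid_frames_break_spans(self):
        clock = clock_30fps(60)
        pos = np.outer(clock.times, [10.0, 0.0, 0.0])
        pos[30] = np.nan
        kin = compute_kinematics(pos, clock, window=5)
        assert not kin[30].valid
        assert kin[29].valid and kin[31].valid

    def test_window_validation(self):
        clock = clock_30fps(10)
        with pytest.raises(ConfigurationError):
            compute_kinematics(np.zeros((10, 3)), clock, window=4)

    def test_approach_rate_sign(self):
        clock = clock_30fps(60)
        pos = np.outer(clock.times, [10.0, 0.0, 0.0])
        dists = 20.0 - 5.0 * clock.times  # approaching at 5 mm/s
        kin = compute_kinematics(pos, clock, window=5, nearest_distances=dists)
        assert np.allclose([k.approach_rate for k in kin[5:-5]], 5.0, atol=1e-6)


# ---------------------------------------------------------------------------
# frame-state rules
# ---------------------------------------------------------------------------

def _records(instrument, dists_by_structure, clock):
    out = []
    for i, t in enumerate(clock.times):
        for name, series in dists_by_structure.items():
            out.append(DistanceRecord(float(t), instrument, name, float(series[i]), False, True))
    return out


def _kin(instrument, clock, speed=0.5):
    return [Kinematics(float(t), instrument, speed, 0.0, True) for t in clock.times]


class TestInferFrameState:
    def test_close_static_grasper(self):
        clock = clock_30fps(3)
        recs = _records("g", {"mesentery": [1.0] * 3}, clock)
        states = infer_frame_state(recs, _kin("g", clock, 0.5), RuleConfig(), {"g": "grasper"})
        s = states[1]
        assert s.target == "mesentery" and s.contact and s.verb == "grasp"
        assert s.confidence >= 2.0 / 3.0 - 1e-9

    def test_hysteresis_no_exit_below_tau_exit(self):
        clock = clock_30fps(3)
        recs = _records("g", {"a": [2.9, 4.0, 2.9]}, clock)
        states = infer_frame_state(recs, _kin("g", clock), RuleConfig(), {"g": "grasper"})
        assert all(s.contact for s in states)

    def test_hysteresis_exit_above_tau_exit(self):
        clock = clock_30fps(3)
        recs = _records("g", {"a": [2.0, 5.5, 4.0]}, clock)
        states = infer_frame_state(recs, _kin("g", clock), RuleConfig(), {"g": "grasper"})
        assert [s.contact for s in states] == [True, False, False]

    def test_tie_broken_by_priority(self):
        clock = clock_30fps(1)
        recs = _records("g", {"zeta": [4.0], "alpha": [4.0]}, clock)
        cfg = RuleConfig(structure_priority=["zeta"])
        states = infer_frame_state(recs, _kin("g", clock), cfg, {"g": "grasper"})
        assert states[0].target == "zeta"
        # without priority: lexicographic
        states2 = infer_frame_state(recs, _kin("g", clock), RuleConfig(), {"g": "grasper"})
        assert states2[0].target == "alpha"

    def test_far_is_idle(self):
        clock = clock_30fps(2)
        recs = _records("g", {"a": [50.0, 50.0]}, clock)
        states = infer_frame_state(recs, _kin("g", clock), RuleConfig(), {"g": "grasper"})
        assert all(s.verb == "idle" and s.target == "none" for s in states)

    def test_hysteresis_sandwich(self):
        """Stricter tau_enter yields a subset of contact frames."""
        clock = clock_30fps(40)
        rng = np.random.default_rng(8)
        series = np.clip(4.0 + np.cumsum(rng.normal(0, 0.8, 40)), 0.5, 30.0)
        recs = _records("g", {"a": series}, clock)
        loose = infer_frame_state(recs, _kin("g", clock), RuleConfig(tau_enter=3.0), {"g": "grasper"})
        strict = infer_frame_state(recs, _kin("g", clock), RuleConfig(tau_enter=1.5), {"g": "grasper"})
        for s_strict, s_loose in zip(strict, loose):
            if s_strict.contact:
                assert s_loose.contact

    def test_missing_verb_table_key(self):
        with pytest.raises(ConfigurationError):
            RuleConfig(verb_table={"grasper": {(True, "static"): "grasp"}})

    def test_unknown_archetype(self):
        clock = clock_30fps(1)
        recs = _records("g", {"a": [1.0]}, clock)
        with pytest.raises(ConfigurationError):
            infer_frame_state(recs, _kin("g", clock), RuleConfig(), {"g": "laser"})


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _states_from_verbs(verbs, clock, instrument="g", target="a"):
    from arlabels.events import FrameState

    return [
        FrameState(float(t), instrument, target if v != "idle" else "none",
                   v != "idle", v, 0.8 if v != "idle" else 0.0, True)
        for t, v in zip(clock.times, verbs)
    ]


class TestAggregateTriplets:
    def test_scripted_contact_recovered(self):
        clock = clock_30fps(120)  # 4 s
        verbs = ["idle"] * 30 + ["grasp"] * 61 + ["idle"] * 29  # 2.0 s contact
        events = aggregate_triplets(_states_from_verbs(verbs, clock), clock, RuleConfig())
        assert len(events) == 1
        e = events[0]
        assert abs(e.t_start - 1.0) <= 1 / 30 + 1e-9
        assert abs(e.t_end - 3.0) <= 1 / 30 + 1e-9

    def test_short_blip_discarded(self):
        clock = clock_30fps(60)
        verbs = ["idle"] * 20 + ["grasp"] * 6 + ["idle"] * 34  # 0.2 s blip
        events = aggregate_triplets(_states_from_verbs(verbs, clock), clock, RuleConfig())
        assert events == []

    def test_gap_merged(self):
        clock = clock_30fps(100)
        verbs = ["grasp"] * 31 + ["idle"] * 3 + ["grasp"] * 31 + ["idle"] * 35
        events = aggregate_triplets(_states_from_verbs(verbs, clock), clock, RuleConfig())
        assert len(events) == 1
        assert events[0].frames == 62

    def test_blip_of_other_verb_bridged(self):
        clock = clock_30fps(100)
        verbs = ["grasp"] * 31 + ["retract"] * 2 + ["grasp"] * 31 + ["idle"] * 36
        events = aggregate_triplets(_states_from_verbs(verbs, clock), clock, RuleConfig())
        assert [e.verb for e in events] == ["grasp"]

    def test_determinism(self, demo_pipeline):
        session, _, _, _, states, events = demo_pipeline
        again = aggregate_triplets(states, session.clock, RuleConfig())
        assert again == events


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def ev(instrument="g", verb="grasp", target="a", t0=0.0, t1=1.0):
    return TripletEvent(instrument, verb, target, t0, t1, 1.0, int((t1 - t0) * 30))


class TestScoreEvents:
    def test_perfect(self):
        truth = [ev(t0=0, t1=1), ev(verb="cut", t0=2, t1=3)]
        p, r, iou = score_events(truth, truth, 0.5)
        assert (p, r, iou) == (1.0, 1.0, 1.0)

    def test_empty_predictions(self):
        p, r, iou = score_events([], [ev()], 0.5)
        assert r == 0.0 and iou == 0.0

    def test_offset_iou_closed_form(self):
        # 10% duration offset: intersection 0.9, union 1.1
        p, r, iou = score_events([ev(t0=0.1, t1=1.1)], [ev(t0=0.0, t1=1.0)], 0.5)
        assert abs(iou - 9.0 / 11.0) < 1e-9
        assert p == 1.0 and r == 1.0

    def test_label_mismatch_never_matches(self):
        p, r, iou = score_events([ev(verb="cut")], [ev(verb="grasp")], 0.5)
        assert p == 0.0 and r == 0.0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            score_events([], [], 0.0)


# ---------------------------------------------------------------------------
# pipeline closure
# ---------------------------------------------------------------------------

class TestPipelineClosure:
    def test_noiseless_demo_perfect(self, demo_pipeline):
        _, truth, _, _, _, events = demo_pipeline
        p, r, iou = score_events(events, truth.contact_events, 0.5)
        assert p == 1.0 and r == 1.0
        assert len(events) == 6

    def test_no_event_target_beyond_tau_far(self, demo_pipeline):
        session, _, records, _, _, events = demo_pipeline
        cfg = RuleConfig()
        by_key = {}
        for rec in records:
            by_key[(rec.instrument, rec.structure, round(rec.t, 6))] = rec
        for e in events:
            near = [
                by_key[(e.instrument, e.target, round(t, 6))].distance
                for t in session.clock.times
                if e.t_start <= t <= e.t_end
            ]
            assert min(near) <= cfg.tau_far

    def test_jittered_demo_iou(self, jitter_pipeline):
        _, truth, events = jitter_pipeline
        for g in truth.contact_events:
            best = max(
                (e.interval_iou(g) for e in events
                 if (e.instrument, e.verb, e.target) == (g.instrument, g.verb, g.target)),
                default=0.0,
            )
            assert best >= 0.8
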