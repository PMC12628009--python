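"""Workflow-level annotations: instrument-structure distance series, tip
kinematics, and rule-based (instrument, verb, target) action triplets.

The closeness metric is the unsigned distance from the instrument *tip*
point to each anatomy mesh, computed in the patient frame for every frame of
the clock regardless of camera visibility — off-screen instruments are
annotated exactly like on-screen ones. A known limitation is reproduced
deliberately: a tool resting on tissue without active engagement still
produces a contact verb, since only proximity, motion direction and tool
speed feed the rules (no force sensing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .geometry import mesh_distance, point_in_mesh
from .replay import DEFAULT_MAX_GAP, Replayer
from .session import FrameClock, Session

__all__ = [
    "DistanceRecord",
    "Kinematics",
    "RuleConfig",
    "FrameState",
    "TripletEvent",
    "DEFAULT_VERB_TABLE",
    "IDLE_VERB",
    "NULL_TARGET",
    "compute_distance_series",
    "compute_kinematics",
    "infer_frame_state",
    "aggregate_triplets",
    "infer_session_triplets",
    "score_events",
    "write_distances_csv",
    "write_triplets_json",
    "read_triplets_json",
]

IDLE_VERB = "idle"
NULL_TARGET = "none"

SPEED_CLASSES = ("static", "moving", "fast")

# Default vocabulary per instrument archetype, keyed by
# (in_contact, speed_class). Non-contact frames map to the idle verb and are
# never exported as events. Fully overridable through RuleConfig.
DEFAULT_VERB_TABLE: dict[str, dict[tuple[bool, str], str]] = {
    "grasper": {
        (True, "static"): "grasp",
        (True, "moving"): "grasp",
        (True, "fast"): "retract",
    },
    "scissors": {
        (True, "static"): "cut",
        (True, "moving"): "cut",
        (True, "fast"): "cut",
    },
    "hook": {
        (True, "static"): "dissect",
        (True, "moving"): "dissect",
        (True, "fast"): "dissect",
    },
    "stapler": {
        (True, "static"): "staple",
        (True, "moving"): "staple",
        (True, "fast"): "staple",
    },
}
for _table in DEFAULT_VERB_TABLE.values():
    for _cls in SPEED_CLASSES:
        _table[(False, _cls)] = IDLE_VERB


@dataclass(frozen=True)
class DistanceRecord:
    t: float
    instrument: str
    structure: str
    distance: float          # mm, unsigned; NaN when invalid
    inside: bool
    valid: bool


@dataclass(frozen=True)
class Kinematics:
    t: float
    instrument: str
    speed: float             # mm/s
    approach_rate: float     # mm/s toward the current nearest structure (+ = approaching)
    valid: bool


@dataclass
class RuleConfig:
    """Thresholds and vocabulary of the rule-based triplet model.

    ``kinematics_window`` (frames, odd) is the span of the local linear fit
    used for speeds; 15 frames (0.5 s at 30 fps) keeps speed classes stable
    under millimetre-level tracking jitter.
    """

    tau_enter: float = 3.0       # mm — contact enters below this
    tau_exit: float = 5.0        # mm — contact exits above this (hysteresis)
    tau_far: float = 20.0        # mm — beyond this: null target, idle verb
    s_static: float = 2.0        # mm/s
    s_active: float = 8.0        # mm/s
    min_duration: float = 0.5    # s
    merge_gap: float = 0.2       # s
    kinematics_window: int = 15  # frames
    structure_priority: list[str] = dc_field(default_factory=list)
    verb_table: dict[str, dict[tuple[bool, str], str]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VERB_TABLE.items()}
    )

    def __post_init__(self):
        if not self.tau_enter < self.tau_exit < self.tau_far:
            raise ConfigurationError("require tau_enter < tau_exit < tau_far")
        if self.min_duration <= 0:
            raise ConfigurationError("min_duration must be > 0")
        if self.kinematics_window < 3 or self.kinematics_window % 2 == 0:
            raise ConfigurationError("kinematics_window must be odd and >= 3")
        for archetype, table in self.verb_table.items():
            for contact in (True, False):
                for cls in SPEED_CLASSES:
                    if (contact, cls) not in table:
                        raise ConfigurationError(
                            f"verb_table['{archetype}'] missing key ({contact}, '{cls}')"
                        )

    def speed_class(self, speed: float) -> str:
        if speed < self.s_static:
            return "static"
        if speed <= self.s_active:
            return "moving"
        return "fast"

    def verbs_for(self, archetype: str) -> dict[tuple[bool, str], str]:
        if archetype not in self.verb_table:
            raise ConfigurationError(f"no verb table for instrument archetype '{archetype}'")
        return self.verb_table[archetype]


@dataclass(frozen=True)
class FrameState:
    t: float
    instrument: str
    target: str              # structure name or NULL_TARGET
    contact: bool
    verb: str
    confidence: float
    valid: bool


@dataclass(frozen=True)
class TripletEvent:
    instrument: str
    verb: str
    target: str
    t_start: float
    t_end: float
    mean_confidence: float
    frames: int

    def interval_iou(self, other: "TripletEvent") -> float:
        lo = max(self.t_start, other.t_start)
        hi = min(self.t_end, other.t_end)
        inter = max(0.0, hi - lo)
        union = (self.t_end - self.t_start) + (other.t_end - other.t_start) - inter
        return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# distance series
# ---------------------------------------------------------------------------

def compute_distance_series(
    session: Session,
    clock: FrameClock | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
) -> list[DistanceRecord]:
    """Per frame x instrument x anatomy tip-to-mesh distances in the patient
    frame. Frames whose tip chain is invalid yield invalid records; camera
    visibility plays no role here."""
    clock = clock if clock is not None else session.clock
    replayer = Replayer(session, max_gap=max_gap)

    # anatomy meshes in the patient frame; static paths are resolved once
    placed = []
    for anat in session.anatomies:
        pose, valid = replayer.resolve_at_frame(0, session.patient_frame, anat.frame)
        mesh = anat.mesh if anat.frame == session.patient_frame else anat.mesh.transformed(pose)
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        placed.append((anat.name, mesh, lo, hi))

    records: list[DistanceRecord] = []
    for fi, t in enumerate(clock.times):
        for inst in session.instruments:
            tip, valid = replayer.tip_position_at_frame(fi, inst)
            for name, mesh, lo, hi in placed:
                if not valid:
                    records.append(
                        DistanceRecord(float(t), inst.name, name, float("nan"), False, False)
                    )
                    continue
                d, _, _ = mesh_distance(tip, mesh)
                inside = False
                if np.all(tip >= lo) and np.all(tip <= hi) and mesh.is_watertight:
                    inside = point_in_mesh(tip, mesh)
                records.append(DistanceRecord(float(t), inst.name, name, d, inside, True))
    return records


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _windowed_slopes(times: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Local least-squares slope of ``values`` (N,) or (N, D) over a centred
    window; reduces to a central finite difference for window 3 and to a
    one-sided difference at span endpoints."""
    n = len(times)
    vals = values if values.ndim == 2 else values[:, None]
    out = np.zeros_like(vals, dtype=np.float64)
    half = window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        tt = times[lo:hi]
        vv = vals[lo:hi]
        if len(tt) < 2:
            out[i] = 0.0
            continue
        tc = tt - tt.mean()
        denom = float(np.dot(tc, tc))
        if denom == 0.0:
            out[i] = 0.0
            continue
        out[i] = (tc[:, None] * (vv - vv.mean(axis=0))).sum(axis=0) / denom
    return out if values.ndim == 2 else out[:, 0]


def compute_kinematics(
    tip_positions: np.ndarray,
    clock: FrameClock,
    window: int = 15,
    nearest_distances: np.ndarray | None = None,
    instrument: str = "",
) -> list[Kinematics]:
    """Tip speed and approach rate from per-frame positions.

    ``tip_positions`` is (N, 3) with NaN rows for invalid frames; invalid
    frames break the differentiation spans. ``nearest_distances`` (N,) feeds
    ``approach_rate`` = -d/dt(distance-to-nearest); without it the rate is 0.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    pos = np.asarray(tip_positions, dtype=np.float64).reshape(-1, 3)
    n = len(pos)
    times = clock.times[:n]
    valid = ~np.isnan(pos).any(axis=1)
    speed = np.zeros(n)
    approach = np.zeros(n)
    dn = None
    if nearest_distances is not None:
        dn = np.asarray(nearest_distances, dtype=np.float64).reshape(-1)

    # split into maximal valid spans
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        vel = _windowed_slopes(times[i:j], pos[i:j], window)
        speed[i:j] = np.linalg.norm(vel, axis=1)
        if dn is not None:
            dd = dn[i:j]
            good = ~np.isnan(dd)
            if good.all() and len(dd) >= 2:
                approach[i:j] = -_windowed_slopes(times[i:j], dd, window)
        i = j
    return [
        Kinematics(float(times[k]), instrument, float(speed[k]), float(approach[k]), bool(valid[k]))
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# rule-based frame states and events
# ---------------------------------------------------------------------------

def _nearest_structure(dists: dict[str, float], config: RuleConfig) -> tuple[str, float]:
    """Minimal-distance structure; ties broken by structure_priority order,
    then lexicographic name order."""
    best = min(dists.values())
    tied = sorted(name for name, d in dists.items() if d == best)
    if len(tied) > 1:
        for name in config.structure_priority:
            if name in tied:
                return name, best
    return tied[0], best


def infer_frame_state(
    distances: list[DistanceRecord],
    kinematics: list[Kinematics],
    config: RuleConfig,
    archetypes: dict[str, str] | None = None,
) -> list[FrameState]:
    """Per-frame, per-instrument rule evaluation.

    ``distances`` and ``kinematics`` must share the frame clock. Contact uses
    enter/exit hysteresis on the distance to the per-frame nearest structure;
    confidence is ``max(0, 1 - d / tau_enter)`` while in contact, else 0.
    """
    archetypes = archetypes or {}
    by_frame: dict[str, dict[float, dict[str, DistanceRecord]]] = {}
    for rec in distances:
        by_frame.setdefault(rec.instrument, {}).setdefault(rec.t, {})[rec.structure] = rec
    kin_by_inst: dict[str, dict[float, Kinematics]] = {}
    for k in kinematics:
        kin_by_inst.setdefault(k.instrument, {})[k.t] = k

    states: list[FrameState] = []
    for instrument in sorted(by_frame):
        table = config.verbs_for(archetypes.get(instrument, "grasper"))
        in_contact = False
        for t in sorted(by_frame[instrument]):
            recs = by_frame[instrument][t]
            if not all(r.valid for r in recs.values()):
                states.append(
                    FrameState(t, instrument, NULL_TARGET, False, IDLE_VERB, 0.0, valid=False)
                )
                continue
            target, dmin = _nearest_structure(
                {name: r.distance for name, r in recs.items()}, config
            )
            if in_contact:
                if dmin > config.tau_exit:
                    in_contact = False
            else:
                if dmin < config.tau_enter:
                    in_contact = True
            if dmin > config.tau_far:
                in_contact = False
                states.append(FrameState(t, instrument, NULL_TARGET, False, IDLE_VERB, 0.0, True))
                continue
            kin = kin_by_inst.get(instrument, {}).get(t)
            speed = kin.speed if kin is not None and kin.valid else 0.0
            verb = table[(in_contact, config.speed_class(speed))]
            conf = max(0.0, 1.0 - dmin / config.tau_enter) if in_contact else 0.0
            states.append(FrameState(t, instrument, target, in_contact, verb, conf, True))
    return states


def aggregate_triplets(
    frame_states: list[FrameState], clock: FrameClock, config: RuleConfig
) -> list[TripletEvent]:
    """Maximal runs of identical (instrument, verb, target) become events;
    identical events separated by gaps <= merge_gap are merged; events
    shorter than min_duration are discarded, as are idle/null events
    (which remain in the per-frame table)."""
    by_inst: dict[str, list[FrameState]] = {}
    for s in frame_states:
        by_inst.setdefault(s.instrument, []).append(s)

    events: list[TripletEvent] = []
    for instrument in sorted(by_inst):
        seq = sorted(by_inst[instrument], key=lambda s: s.t)
        runs: list[dict] = []
        cur: dict | None = None
        for s in seq:
            usable = s.valid and s.verb != IDLE_VERB and s.target != NULL_TARGET
            if not usable:
                cur = None
                continue
            key = (s.verb, s.target)
            if cur is not None and cur["key"] == key:
                cur["t_end"] = s.t
                cur["conf"].append(s.confidence)
                cur["frames"] += 1
            else:
                cur = {"key": key, "t_start": s.t, "t_end": s.t, "conf": [s.confidence], "frames": 1}
                runs.append(cur)
        # merge identical runs across short gaps (gaps may contain brief
        # runs of other labels — e.g. single-frame speed-class blips)
        by_key: dict[tuple, list[dict]] = {}
        for run in runs:
            bucket = by_key.setdefault(run["key"], [])
            if bucket and run["t_start"] - bucket[-1]["t_end"] <= config.merge_gap + 1e-9:
                bucket[-1]["t_end"] = run["t_end"]
                bucket[-1]["conf"] += run["conf"]
                bucket[-1]["frames"] += run["frames"]
            else:
                bucket.append(run)
        merged = sorted(
            (run for bucket in by_key.values() for run in bucket), key=lambda r: r["t_start"]
        )
        for run in merged:
            if run["t_end"] - run["t_start"] < config.min_duration:
                continue
            verb, target = run["key"]
            events.append(
                TripletEvent(
                    instrument=instrument,
                    verb=verb,
                    target=target,
                    t_start=float(run["t_start"]),
                    t_end=float(run["t_end"]),
                    mean_confidence=float(np.mean(run["conf"])),
                    frames=int(run["frames"]),
                )
            )
    events.sort(key=lambda e: (e.t_start, e.instrument))
    return events


def score_events(
    predicted: list[TripletEvent], truth: list[TripletEvent], iou_threshold: float = 0.5
) -> tuple[float, float, float]:
    """Greedy matching by descending interval IoU among label-identical
    (instrument, verb, target) pairs. Returns (precision, recall, mean IoU
    over matched pairs)."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    pairs = []
    for i, p in enumerate(predicted):
        for j, g in enumerate(truth):
            if (p.instrument, p.verb, p.target) == (g.instrument, g.verb, g.target):
                iou = p.interval_iou(g)
                if iou >= iou_threshold:
                    pairs.append((iou, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p, used_t = set(), set()
    ious = []
    for iou, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        ious.append(iou)
    n_match = len(ious)
    precision = n_match / len(predicted) if predicted else 1.0
    recall = n_match / len(truth) if truth else 1.0
    mean_iou = float(np.mean(ious)) if ious else 0.0
    return precision, recall, mean_iou


# ---------------------------------------------------------------------------
# whole-session pipeline
# ---------------------------------------------------------------------------

def infer_session_triplets(
    session: Session,
    config: RuleConfig | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
):
    """Distances -> kinematics -> frame states -> events for a whole session.

    Returns ``(records, kinematics, frame_states, events)``.
    """
    config = config if config is not None else RuleConfig()
    records = compute_distance_series(session, max_gap=max_gap)
    clock = session.clock
    replayer = Replayer(session, max_gap=max_gap)

    dmin_by_inst: dict[str, dict[float, float]] = {}
    for r in records:
        d = dmin_by_inst.setdefault(r.instrument, {})
        prev = d.get(r.t)
        val = r.distance if r.valid else float("nan")
        d[r.t] = val if prev is None else min(prev, val)

    kinematics: list[Kinematics] = []
    for inst in session.instruments:
        tips = np.full((len(clock), 3), np.nan)
        for fi in range(len(clock)):
            p, ok = replayer.tip_position_at_frame(fi, inst)
            if ok:
                tips[fi] = p
        dmin = np.array([dmin_by_inst[inst.name].get(float(t), np.nan) for t in clock.times])
        kinematics += compute_kinematics(
            tips, clock, config.kinematics_window, nearest_distances=dmin, instrument=inst.name
        )

    archetypes = {i.name: i.archetype for i in session.instruments}
    states = infer_frame_state(records, kinematics, config, archetypes)
    events = aggregate_triplets(states, clock, config)
    return records, kinematics, states, events


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_distances_csv(records: list[DistanceRecord], path) -> None:
    lines = ["t,instrument,structure,distance_mm,inside,valid"]
    for r in records:
        d = "nan" if np.isnan(r.distance) else f"{r.distance:.9g}"
        lines.append(
            f"{r.t:.9g},{r.instrument},{r.structure},{d},{1 if r.inside else 0},{1 if r.valid else 0}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _config_echo(config: RuleConfig) -> dict:
    d = asdict(config)
    d["verb_table"] = {
        arch: {f"{int(c)}|{cls}": verb for (c, cls), verb in sorted(table.items(), key=str)}
        for arch, table in sorted(config.verb_table.items())
    }
    return d


def write_triplets_json(
    events: list[TripletEvent], path, config: RuleConfig | None = None, session_id: str = ""
) -> None:
    payload = {
        "session_id": session_id,
        "config": _config_echo(config) if config is not None else None,
        "events": [
            {
                "instrument": e.instrument,
                "verb": e.verb,
                "target": e.target,
                "t_start": round(e.t_start, 9),
                "t_end": round(e.t_end, 9),
                "mean_confidence": round(e.mean_confidence, 9),
                "frames": e.frames,
            }
            for e in events
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_triplets_json(path) -> list[TripletEvent]:
    payload = json.loads(Path(path).read_text())
    return [
        TripletEvent(
            instrument=e["instrument"],
            verb=e["verb"],
            target=e["target"],
            t_start=float(e["t_start"]),
            t_end=float(e["t_end"]),
            mean_confidence=float(e["mean_confidence"]),
            frames=int(e["frames"]),
        )
        for e in payload["events"]
    ]
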