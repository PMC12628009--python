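"""Time-synchronized replay: stream resampling onto the frame clock and
frame-to-frame transform resolution through the session frame graph.

Gap policy: interpolation only between bracketing *valid* samples whose
spacing is at most ``max_gap`` (default 0.2 s — longer gaps imply an
occluded tracking array and interpolating across them would fabricate
data). Queries beyond the stream ends are clamped only within half the
median sample interval; everything else is an explicit, invalid ``gap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DisconnectedFramesError, EmptyClockError, UnknownFrameError
from .geometry import RigidTransform, compose, interpolate_pose, invert
from .session import FrameClock, Session, StaticEdge, TransformStream

__all__ = [
    "ResampledPose",
    "ResolvedScene",
    "resample_stream",
    "resolve_transform",
    "resolve_scene",
    "Replayer",
    "DEFAULT_MAX_GAP",
]

DEFAULT_MAX_GAP = 0.2   # s
EXACT_TOL = 1e-9        # s


@dataclass(frozen=True)
class ResampledPose:
    t: float
    pose: RigidTransform | None     # None when source == "gap"
    valid: bool
    source: str                     # "exact" | "interpolated" | "gap"


@dataclass(frozen=True)
class ResolvedScene:
    t: float
    root_frame: str
    poses: dict[str, tuple[RigidTransform | None, bool]]


def _stream_pose_at(stream: TransformStream, t: float, max_gap: float) -> ResampledPose:
    times = stream.times
    j = int(np.searchsorted(times, t))
    for cand in (j - 1, j):
        if 0 <= cand < len(times) and abs(times[cand] - t) <= EXACT_TOL and stream.valid[cand]:
            return ResampledPose(t=t, pose=stream.pose(cand), valid=True, source="exact")

    vidx = np.flatnonzero(stream.valid)
    if len(vidx) == 0:
        return ResampledPose(t=t, pose=None, valid=False, source="gap")
    vt = times[vidx]
    k = int(np.searchsorted(vt, t))

    if len(times) > 1:
        half_med = 0.5 * float(np.median(np.diff(times)))
    else:
        half_med = 0.0
    # clamp just beyond the stream ends (within half the median interval)
    if t < times[0]:
        if times[0] - t <= half_med + EXACT_TOL and stream.valid[0]:
            return ResampledPose(t=t, pose=stream.pose(0), valid=True, source="interpolated")
        return ResampledPose(t=t, pose=None, valid=False, source="gap")
    if t > times[-1]:
        if t - times[-1] <= half_med + EXACT_TOL and stream.valid[-1]:
            return ResampledPose(t=t, pose=stream.pose(-1), valid=True, source="interpolated")
        return ResampledPose(t=t, pose=None, valid=False, source="gap")

    if k == 0 or k == len(vt):  # inside stream span but no valid bracket on one side
        return ResampledPose(t=t, pose=None, valid=False, source="gap")
    i0, i1 = vidx[k - 1], vidx[k]
    if times[i1] - times[i0] > max_gap + EXACT_TOL:
        return ResampledPose(t=t, pose=None, valid=False, source="gap")
    pose = interpolate_pose(times[i0], stream.pose(i0), times[i1], stream.pose(i1), t)
    return ResampledPose(t=t, pose=pose, valid=True, source="interpolated")


def resample_stream(
    stream: TransformStream, times: FrameClock, max_gap: float = DEFAULT_MAX_GAP
) -> list[ResampledPose]:
    """Resample a transform stream onto a frame clock."""
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    if len(times) == 0:
        raise EmptyClockError("cannot resample onto an empty clock")
    return [_stream_pose_at(stream, float(t), max_gap) for t in times.times]


# ---------------------------------------------------------------------------
# frame-graph resolution
# ---------------------------------------------------------------------------

def _adjacency(session: Session):
    adj: dict[str, list[tuple[str, object, bool]]] = {f: [] for f in session.frames}
    for parent, child, payload in session.edges():
        adj[parent].append((child, payload, False))   # along stored direction
        adj[child].append((parent, payload, True))    # inverted traversal
    return adj


def _find_path(session: Session, frame_a: str, frame_b: str):
    """Breadth-first path from a to b. Returns a list of (payload, inverted)
    steps such that composing payload poses (child-in-parent) yields T_a<-b."""
    for f in (frame_a, frame_b):
        if f not in session.frames:
            raise UnknownFrameError(f"unknown frame '{f}'")
    if frame_a == frame_b:
        return []
    adj = _adjacency(session)
    prev: dict[str, tuple[str, object, bool]] = {frame_a: None}
    queue = [frame_a]
    while queue:
        cur = queue.pop(0)
        if cur == frame_b:
            break
        for nxt, payload, inverted in adj[cur]:
            if nxt not in prev:
                prev[nxt] = (cur, payload, inverted)
                queue.append(nxt)
    if frame_b not in prev:
        raise DisconnectedFramesError(f"no path between '{frame_a}' and '{frame_b}'")
    steps = []
    cur = frame_b
    while cur != frame_a:
        parent, payload, inverted = prev[cur]
        steps.append((payload, inverted))
        cur = parent
    steps.reverse()
    return steps


def _edge_pose(payload, t: float, max_gap: float):
    if isinstance(payload, StaticEdge):
        return payload.transform, True
    rp = _stream_pose_at(payload, t, max_gap)
    return rp.pose, rp.valid


def resolve_transform(
    session: Session, frame_a: str, frame_b: str, t: float, max_gap: float = DEFAULT_MAX_GAP
) -> tuple[RigidTransform | None, bool]:
    """Transform mapping points in ``frame_b`` into ``frame_a`` at time ``t``.

    Composes edges along the unique BFS path, inverting edges traversed
    against their stored (parent -> child) direction. The result is invalid
    iff any dynamic edge on the path is invalid at ``t``; static edges are
    always valid.
    """
    steps = _find_path(session, frame_a, frame_b)
    result = RigidTransform.identity()
    for payload, inverted in steps:
        pose, valid = _edge_pose(payload, t, max_gap)
        if not valid:
            return None, False
        result = compose(result, invert(pose) if inverted else pose)
    return result, True


def scene_frames(session: Session) -> list[str]:
    """Frames of interest for per-frame annotation: camera optical frame,
    each instrument tip, each anatomy frame."""
    frames = [session.camera_frame]
    frames += [inst.tip_frame for inst in session.instruments]
    frames += [a.frame for a in session.anatomies]
    seen = set()
    out = []
    for f in frames:
        if f not in seen:
            seen.add(f)
            out.append(f)
    return out


def resolve_scene(
    session: Session, t: float, root_frame: str | None = None, max_gap: float = DEFAULT_MAX_GAP
) -> ResolvedScene:
    """Resolve poses of all frames of interest relative to ``root_frame``
    (default: the patient frame, so anatomy stays static while instruments
    and the camera move — mirroring a table-anchored setup).

    Instrument tip frames are virtual: the instrument array pose composed
    with the static tip-offset translation.
    """
    root = root_frame if root_frame is not None else session.patient_frame
    if root not in session.frames:
        raise UnknownFrameError(f"unknown root frame '{root}'")
    poses: dict[str, tuple[RigidTransform | None, bool]] = {root: (RigidTransform.identity(), True)}
    tip_offsets = {inst.tip_frame: (inst.array_frame, inst.tip_offset) for inst in session.instruments}
    for f in scene_frames(session):
        if f == root:
            continue
        if f in tip_offsets:
            array_frame, offset = tip_offsets[f]
            base, valid = resolve_transform(session, root, array_frame, t, max_gap)
            if valid:
                tip = compose(base, RigidTransform([1.0, 0.0, 0.0, 0.0], offset))
                poses[f] = (tip, True)
            else:
                poses[f] = (None, False)
        else:
            poses[f] = resolve_transform(session, root, f, t, max_gap)
    return ResolvedScene(t=t, root_frame=root, poses=poses)


class Replayer:
    """Caches per-edge resampled poses on the frame clock for fast per-frame
    scene resolution. Results are identical to calling
    :func:`resolve_transform` at each clock time."""

    def __init__(self, session: Session, max_gap: float = DEFAULT_MAX_GAP):
        self.session = session
        self.max_gap = max_gap
        self._paths: dict[tuple[str, str], list] = {}
        self._edge_cache: dict[int, list[ResampledPose]] = {}
        if len(session.clock) == 0:
            raise EmptyClockError("session has an empty frame clock")
        for s in session.streams:
            self._edge_cache[id(s)] = resample_stream(s, session.clock, max_gap)

    def resolve_at_frame(self, frame_idx: int, frame_a: str, frame_b: str):
        key = (frame_a, frame_b)
        if key not in self._paths:
            self._paths[key] = _find_path(self.session, frame_a, frame_b)
        result = RigidTransform.identity()
        for payload, inverted in self._paths[key]:
            if isinstance(payload, StaticEdge):
                pose, valid = payload.transform, True
            else:
                rp = self._edge_cache[id(payload)][frame_idx]
                pose, valid = rp.pose, rp.valid
            if not valid:
                return None, False
            result = compose(result, invert(pose) if inverted else pose)
        return result, True

    def tip_position_at_frame(self, frame_idx: int, instrument, root_frame: str | None = None):
        """Instrument tip point in ``root_frame`` (default patient frame)."""
        root = root_frame if root_frame is not None else self.session.patient_frame
        base, valid = self.resolve_at_frame(frame_idx, root, instrument.array_frame)
        if not valid:
            return None, False
        return base.apply(instrument.tip_offset), True
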