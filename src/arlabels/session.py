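"""Portable session format: manifest + transform streams + meshes + frame clock.

A session directory looks like::

    manifest.json            # frame graph, calibrations, camera, inventory
    frames.csv               # video frame clock (column: t)
    streams/<name>.csv       # t,qw,qx,qy,qz,tx,ty,tz,valid
    meshes/<name>.ply        # anatomy meshes, patient coordinates

All timestamps are session-relative seconds starting at 0.0 and shared by
every stream. Writing is deterministic: stable key ordering and floats at 9
significant digits, so identical in-memory sessions produce byte-identical
directories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .errors import (
    DuplicateEdgeError,
    DuplicateLabelError,
    ManifestError,
    MissingFileError,
    UnknownFrameError,
    UnsortedStreamError,
)
from .geometry import RigidTransform, TriangleMesh
from .meshio import load_mesh, save_ply
from .rendering import CameraModel

__all__ = [
    "FrameClock",
    "TransformStream",
    "StaticEdge",
    "Anatomy",
    "Instrument",
    "Session",
    "ValidationReport",
    "Finding",
    "load_session",
    "write_session",
    "validate_session",
    "sessions_equal",
]

STREAM_HEADER = "t,qw,qx,qy,qz,tx,ty,tz,valid"


def _f9(x: float) -> str:
    return f"{float(x):.9g}"


def _round9(obj):
    """Recursively round floats to 9 significant digits for JSON output."""
    if isinstance(obj, float):
        return float(_f9(obj))
    if isinstance(obj, dict):
        return {k: _round9(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round9(v) for v in obj]
    return obj


@dataclass
class FrameClock:
    times: np.ndarray            # strictly increasing, seconds
    nominal_rate: float          # Hz

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64).reshape(-1)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise UnsortedStreamError("frame clock timestamps must be strictly increasing")

    def __len__(self):
        return len(self.times)


@dataclass
class TransformStream:
    name: str
    parent_frame: str
    child_frame: str
    times: np.ndarray            # (N,)
    quaternions: np.ndarray      # (N, 4) w,x,y,z
    translations: np.ndarray     # (N, 3) mm
    valid: np.ndarray            # (N,) bool

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64).reshape(-1)
        self.quaternions = np.asarray(self.quaternions, dtype=np.float64).reshape(-1, 4)
        self.translations = np.asarray(self.translations, dtype=np.float64).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        n = len(self.times)
        if n < 1:
            raise UnsortedStreamError(f"stream '{self.name}': needs >= 1 sample")
        if not (len(self.quaternions) == len(self.translations) == len(self.valid) == n):
            raise UnsortedStreamError(f"stream '{self.name}': ragged columns")
        if np.any(np.diff(self.times) <= 0):
            raise UnsortedStreamError(f"stream '{self.name}': timestamps not strictly increasing")

    def pose(self, i: int) -> RigidTransform:
        return RigidTransform(self.quaternions[i], self.translations[i])


@dataclass(frozen=True)
class StaticEdge:
    name: str
    parent_frame: str
    child_frame: str
    transform: RigidTransform


@dataclass
class Anatomy:
    name: str
    label_id: int
    frame: str
    mesh: TriangleMesh
    mesh_file: str


@dataclass
class Instrument:
    name: str
    archetype: str               # grasper | scissors | hook | stapler | ...
    array_frame: str
    tip_offset: np.ndarray       # mm, in the array frame
    tool_radius: float           # mm
    verbs: list[str] = dc_field(default_factory=list)
    shaft_mesh_file: str | None = None
    shaft_mesh: TriangleMesh | None = None

    def __post_init__(self):
        self.tip_offset = np.asarray(self.tip_offset, dtype=np.float64).reshape(3)

    @property
    def tip_frame(self) -> str:
        return f"{self.name}_tip"


@dataclass
class Session:
    session_id: str
    frames: list[str]
    static_edges: list[StaticEdge]
    streams: list[TransformStream]
    camera: CameraModel
    camera_frame: str
    patient_frame: str
    anatomies: list[Anatomy]
    instruments: list[Instrument]
    clock: FrameClock

    def __post_init__(self):
        self._check_graph()

    # -- invariants ----------------------------------------------------------
    def _check_graph(self):
        frames = set(self.frames)
        for name in (self.camera_frame, self.patient_frame):
            if name not in frames:
                raise UnknownFrameError(f"frame '{name}' not declared in frame list")
        seen_pairs = set()
        for edge in self.edges():
            for f in (edge[0], edge[1]):
                if f not in frames:
                    raise UnknownFrameError(f"edge references undeclared frame '{f}'")
            key = frozenset((edge[0], edge[1]))
            if key in seen_pairs:
                raise DuplicateEdgeError(f"duplicate edge between {set(key)}")
            seen_pairs.add(key)
        labels = {}
        for a in self.anatomies:
            if not 1 <= a.label_id <= 255:
                raise DuplicateLabelError(f"label_id {a.label_id} outside [1, 255]")
            if a.label_id in labels:
                raise DuplicateLabelError(
                    f"label_id {a.label_id} used by both '{labels[a.label_id]}' and '{a.name}'"
                )
            labels[a.label_id] = a.name
            if a.frame not in frames:
                raise UnknownFrameError(f"anatomy '{a.name}' frame '{a.frame}' undeclared")
        for inst in self.instruments:
            if inst.array_frame not in frames:
                raise UnknownFrameError(
                    f"instrument '{inst.name}' array frame '{inst.array_frame}' undeclared"
                )

    def edges(self):
        """All (parent, child, payload) edges; payload is a StaticEdge or a
        TransformStream."""
        out = []
        for e in self.static_edges:
            out.append((e.parent_frame, e.child_frame, e))
        for s in self.streams:
            out.append((s.parent_frame, s.child_frame, s))
        return out

    def connected_components(self) -> list[set[str]]:
        adj = {f: set() for f in self.frames}
        for p, c, _ in self.edges():
            adj[p].add(c)
            adj[c].add(p)
        seen, comps = set(), []
        for f in self.frames:
            if f in seen:
                continue
            comp, stack = set(), [f]
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        return comps


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _write_stream_csv(stream: TransformStream, path: Path) -> None:
    lines = [STREAM_HEADER]
    for i in range(len(stream.times)):
        q = stream.quaternions[i]
        t = stream.translations[i]
        lines.append(
            f"{_f9(stream.times[i])},{_f9(q[0])},{_f9(q[1])},{_f9(q[2])},{_f9(q[3])},"
            f"{_f9(t[0])},{_f9(t[1])},{_f9(t[2])},{1 if stream.valid[i] else 0}"
        )
    path.write_text("\n".join(lines) + "\n")


def _read_stream_csv(path: Path, name: str, parent: str, child: str) -> TransformStream:
    if not path.exists():
        raise MissingFileError(f"stream file not found: {path}")
    raw = path.read_text().strip().splitlines()
    if not raw or raw[0].strip() != STREAM_HEADER:
        raise ManifestError(f"{path}: bad stream header")
    data = np.array(
        [[float(x) for x in line.split(",")] for line in raw[1:]], dtype=np.float64
    ).reshape(-1, 9)
    return TransformStream(
        name=name,
        parent_frame=parent,
        child_frame=child,
        times=data[:, 0],
        quaternions=data[:, 1:5],
        translations=data[:, 5:8],
        valid=data[:, 8] > 0.5,
    )


def write_session(session: Session, path) -> None:
    """Serialize a session directory (deterministic byte layout)."""
    root = Path(path)
    (root / "streams").mkdir(parents=True, exist_ok=True)
    (root / "meshes").mkdir(exist_ok=True)

    manifest = {
        "session_id": session.session_id,
        "frames": list(session.frames),
        "patient_frame": session.patient_frame,
        "camera_frame": session.camera_frame,
        "camera": session.camera.to_dict(),
        "static_edges": [
            {
                "name": e.name,
                "parent_frame": e.parent_frame,
                "child_frame": e.child_frame,
                "quaternion": e.transform.quaternion.tolist(),
                "translation": e.transform.translation.tolist(),
            }
            for e in session.static_edges
        ],
        "dynamic_edges": [
            {
                "stream_file": f"streams/{s.name}.csv",
                "parent_frame": s.parent_frame,
                "child_frame": s.child_frame,
            }
            for s in session.streams
        ],
        "anatomies": [
            {
                "name": a.name,
                "label_id": a.label_id,
                "frame": a.frame,
                "mesh_file": a.mesh_file,
            }
            for a in session.anatomies
        ],
        "instruments": [
            {
                "name": i.name,
                "archetype": i.archetype,
                "array_frame": i.array_frame,
                "tip_offset": i.tip_offset.tolist(),
                "tool_radius": i.tool_radius,
                "verbs": list(i.verbs),
                **({"shaft_mesh_file": i.shaft_mesh_file} if i.shaft_mesh_file else {}),
            }
            for i in session.instruments
        ],
        "frame_clock": {"file": "frames.csv", "nominal_rate": session.clock.nominal_rate},
    }
    (root / "manifest.json").write_text(
        json.dumps(_round9(manifest), sort_keys=True, indent=1) + "\n"
    )

    clock_lines = ["t"] + [_f9(t) for t in session.clock.times]
    (root / "frames.csv").write_text("\n".join(clock_lines) + "\n")

    for s in session.streams:
        _write_stream_csv(s, root / "streams" / f"{s.name}.csv")
    for a in session.anatomies:
        save_ply(a.mesh, root / a.mesh_file)
    for i in session.instruments:
        if i.shaft_mesh is not None and i.shaft_mesh_file:
            save_ply(i.shaft_mesh, root / i.shaft_mesh_file)


def load_session(path) -> Session:
    """Load and fully validate a session directory."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise MissingFileError(f"manifest not found: {mpath}")
    m = json.loads(mpath.read_text())

    try:
        camera = CameraModel.from_dict(m["camera"])
        static_edges = [
            StaticEdge(
                name=e["name"],
                parent_frame=e["parent_frame"],
                child_frame=e["child_frame"],
                transform=RigidTransform(e["quaternion"], e["translation"]),
            )
            for e in m["static_edges"]
        ]
    except KeyError as exc:
        raise ManifestError(f"manifest missing key: {exc}") from exc

    streams = []
    for d in m["dynamic_edges"]:
        spath = root / d["stream_file"]
        streams.append(
            _read_stream_csv(spath, Path(d["stream_file"]).stem, d["parent_frame"], d["child_frame"])
        )

    anatomies = []
    for a in m["anatomies"]:
        mesh_path = root / a["mesh_file"]
        if not mesh_path.exists():
            raise MissingFileError(f"mesh file not found: {mesh_path}")
        anatomies.append(
            Anatomy(
                name=a["name"],
                label_id=int(a["label_id"]),
                frame=a["frame"],
                mesh=load_mesh(mesh_path, name=a["name"]),
                mesh_file=a["mesh_file"],
            )
        )

    instruments = []
    for i in m["instruments"]:
        shaft_file = i.get("shaft_mesh_file")
        shaft_mesh = None
        if shaft_file:
            spath = root / shaft_file
            if not spath.exists():
                raise MissingFileError(f"shaft mesh not found: {spath}")
            shaft_mesh = load_mesh(spath, name=f"{i['name']}_shaft")
        instruments.append(
            Instrument(
                name=i["name"],
                archetype=i.get("archetype", "grasper"),
                array_frame=i["array_frame"],
                tip_offset=np.array(i["tip_offset"], dtype=np.float64),
                tool_radius=float(i["tool_radius"]),
                verbs=list(i.get("verbs", [])),
                shaft_mesh_file=shaft_file,
                shaft_mesh=shaft_mesh,
            )
        )

    clock_file = root / m["frame_clock"]["file"]
    if not clock_file.exists():
        raise MissingFileError(f"frame clock not found: {clock_file}")
    lines = clock_file.read_text().strip().splitlines()
    if not lines or lines[0].strip() != "t":
        raise ManifestError(f"{clock_file}: bad frame clock header")
    clock = FrameClock(
        times=np.array([float(x) for x in lines[1:]], dtype=np.float64),
        nominal_rate=float(m["frame_clock"]["nominal_rate"]),
    )

    return Session(
        session_id=m["session_id"],
        frames=list(m["frames"]),
        static_edges=static_edges,
        streams=streams,
        camera=camera,
        camera_frame=m["camera_frame"],
        patient_frame=m["patient_frame"],
        anatomies=anatomies,
        instruments=instruments,
        clock=clock,
    )


# ---------------------------------------------------------------------------
# validation (reporting, never raising)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str          # "error" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding]
    coverage: dict[str, float]     # stream name -> fraction of clock with valid pose

    @property
    def n_errors(self) -> int:
        return sum(1 for f in self.findings if f.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for f in self.findings if f.severity == "warning")

    @property
    def exit_code(self) -> int:
        if self.n_errors:
            return 2
        if self.n_warnings:
            return 1
        return 0


def validate_session(session: Session, max_gap: float = 0.2) -> ValidationReport:
    """Pure validation: tracking gaps, connectivity, clock/stream range checks.

    Reports findings, never raises and never mutates the session.
    """
    from .replay import resample_stream  # local import to avoid a cycle

    findings: list[Finding] = []
    coverage: dict[str, float] = {}

    comps = session.connected_components()
    if len(comps) > 1:
        cam_comp = next(c for c in comps if session.camera_frame in c)
        if session.patient_frame not in cam_comp:
            findings.append(
                Finding(
                    "error",
                    "disconnected-frames",
                    f"camera frame '{session.camera_frame}' is disconnected from "
                    f"patient frame '{session.patient_frame}'",
                )
            )
        else:
            findings.append(
                Finding("error", "disconnected-frames", f"frame graph has {len(comps)} components")
            )

    t0, t1 = (session.clock.times[0], session.clock.times[-1]) if len(session.clock) else (0.0, 0.0)
    for s in session.streams:
        if len(session.clock):
            resampled = resample_stream(s, session.clock, max_gap=max_gap)
            cov = float(np.mean([r.valid for r in resampled]))
        else:
            cov = 1.0
        coverage[s.name] = cov
        vt = s.times[s.valid]
        if len(vt) >= 2:
            gaps = np.diff(vt)
            n_gaps = int(np.count_nonzero(gaps > max_gap))
            if n_gaps:
                findings.append(
                    Finding(
                        "warning",
                        "tracking-gap",
                        f"stream '{s.name}': {n_gaps} gap(s) longer than {max_gap} s "
                        f"(largest {gaps.max():.3f} s)",
                    )
                )
        if len(session.clock) and (s.times[0] > t0 + 1e-9 or s.times[-1] < t1 - 1e-9):
            findings.append(
                Finding(
                    "warning",
                    "clock-range",
                    f"stream '{s.name}' spans [{s.times[0]:.3f}, {s.times[-1]:.3f}] s but the "
                    f"frame clock spans [{t0:.3f}, {t1:.3f}] s",
                )
            )
    return ValidationReport(findings=findings, coverage=coverage)


def sessions_equal(a: Session, b: Session, atol: float = 1e-8) -> bool:
    """Field-for-field equality at serialization precision (9 significant
    digits corresponds to absolute differences well below ``atol`` for
    session-scale magnitudes)."""
    if (
        a.session_id != b.session_id
        or a.frames != b.frames
        or a.camera != b.camera
        or a.camera_frame != b.camera_frame
        or a.patient_frame != b.patient_frame
        or len(a.static_edges) != len(b.static_edges)
        or len(a.streams) != len(b.streams)
        or len(a.anatomies) != len(b.anatomies)
        or len(a.instruments) != len(b.instruments)
    ):
        return False
    for ea, eb in zip(a.static_edges, b.static_edges):
        if (ea.name, ea.parent_frame, ea.child_frame) != (eb.name, eb.parent_frame, eb.child_frame):
            return False
        if not ea.transform.isclose(eb.transform, atol=atol):
            return False
    for sa, sb in zip(a.streams, b.streams):
        if (sa.name, sa.parent_frame, sa.child_frame) != (sb.name, sb.parent_frame, sb.child_frame):
            return False
        qa, qb = sa.quaternions, sb.quaternions
        flip = np.sign(np.sum(qa * qb, axis=1))[:, None]
        if not (
            np.allclose(sa.times, sb.times, atol=atol)
            and np.allclose(qa, qb * flip, atol=atol)
            and np.allclose(sa.translations, sb.translations, atol=atol)
            and np.array_equal(sa.valid, sb.valid)
        ):
            return False
    for aa, ab in zip(a.anatomies, b.anatomies):
        if (aa.name, aa.label_id, aa.frame, aa.mesh_file) != (ab.name, ab.label_id, ab.frame, ab.mesh_file):
            return False
        if not (
            np.allclose(aa.mesh.vertices, ab.mesh.vertices, atol=atol)
            and np.array_equal(aa.mesh.faces, ab.mesh.faces)
        ):
            return False
    for ia, ib in zip(a.instruments, b.instruments):
        if (ia.name, ia.archetype, ia.array_frame, ia.verbs) != (ib.name, ib.archetype, ib.array_frame, ib.verbs):
            return False
        if not (
            np.allclose(ia.tip_offset, ib.tip_offset, atol=atol)
            and abs(ia.tool_radius - ib.tool_radius) <= atol
        ):
            return False
    return bool(
        np.allclose(a.clock.times, b.clock.times, atol=atol)
        and abs(a.clock.nominal_rate - b.clock.nominal_rate) <= atol
    )
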