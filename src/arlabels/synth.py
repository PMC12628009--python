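"""Synthetic tracked-surgery sessions with scripted ground truth.

The generator emulates a complete recording: an infrared tracker observing
arrays on the table, the laparoscope and each instrument; static hand-eye,
pivot and patient-registration calibrations; anatomy meshes in patient
coordinates; and a video frame clock. Instrument scripts produce smooth
approach / dwell / retreat trajectories around anatomy primitives so that
true contact intervals, calibrations and sphere silhouettes are all known
analytically.

Randomness is split into named substreams (one per consumer) derived from
the top-level seed via ``numpy.random.SeedSequence(seed).spawn``, in the
fixed order: trajectory jitter, dropouts, registration direction. Toggling
one noise source therefore never changes the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .errors import ScriptError
from .events import DEFAULT_VERB_TABLE, TripletEvent
from .geometry import RigidTransform, compose, invert
from .primitives import capped_tube, icosphere, sphere_chord_tolerance
from .rendering import CameraModel
from .session import (
    Anatomy,
    FrameClock,
    Instrument,
    Session,
    StaticEdge,
    TransformStream,
)

__all__ = [
    "AnatomySpec",
    "ContactSpec",
    "InstrumentScript",
    "NoiseSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_session",
    "perturb_registration",
    "analytic_sphere_silhouette",
    "default_demo_config",
    "simulate_pivot_poses",
    "simulate_handeye_motions",
    "write_truth",
]

TRANSITION_S = 0.5       # approach / retreat duration around each dwell
DEFAULT_CLEARANCE = 1.5  # mm, tip-to-surface during a scripted contact


@dataclass(frozen=True)
class AnatomySpec:
    name: str
    shape: str                   # "sphere" | "tube" | "box"
    size: tuple                  # sphere: (radius,); tube: (radius, length); box: (ex, ey, ez)
    center: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)   # tube axis direction (patient frame)
    label_id: int = 1
    subdivisions: int = 4        # icosphere refinement


@dataclass(frozen=True)
class ContactSpec:
    structure: str
    t_start: float               # s, dwell start
    dwell: float                 # s
    clearance: float = DEFAULT_CLEARANCE
    speed_class: str = "static"  # dwell is stationary; recorded for the truth verb


@dataclass(frozen=True)
class InstrumentScript:
    name: str
    archetype: str               # grasper | scissors | hook | stapler
    rest_position: tuple         # mm, patient frame; > tau_exit + 2 from all structures
    shaft_direction: tuple = (0.3, 0.6, -0.74)  # tip -> handle, patient frame
    tip_offset: tuple = (0.0, 0.0, 150.0)       # mm, array frame
    tool_radius: float = 2.5
    contacts: tuple = ()


@dataclass(frozen=True)
class NoiseSpec:
    jitter_sigma_t: float = 0.0     # mm
    jitter_sigma_r: float = 0.0     # deg
    dropout_prob: float = 0.0
    registration_offset: float = 0.0  # mm

    def __post_init__(self):
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ScriptError("dropout_prob must be in [0, 1)")


@dataclass(frozen=True)
class SynthConfig:
    duration: float = 60.0
    tracking_rate: float = 60.0
    frame_rate: float = 30.0
    scene: tuple = ()
    instruments: tuple = ()
    camera_look_from: tuple = (0.0, 0.0, -150.0)
    camera_look_at: tuple = (0.0, 0.0, 10.0)
    camera_orbit_mm: float = 8.0
    camera_orbit_period: float = 25.0
    camera: CameraModel = dc_field(
        default_factory=lambda: CameraModel(fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480)
    )
    noise: NoiseSpec = dc_field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.tracking_rate <= 0 or self.frame_rate <= 0:
            raise ScriptError("rates must be > 0")


@dataclass
class GroundTruth:
    contact_events: list[TripletEvent]
    true_hand_eye: RigidTransform            # array frame -> camera optical frame
    true_tip_offsets: dict[str, np.ndarray]
    true_registration: RigidTransform        # patient-in-table static edge
    spheres: dict[str, tuple[np.ndarray, float]]   # name -> (center patient frame, radius)
    chord_tolerances: dict[str, float]
    tip_paths: dict[str, object]             # name -> callable t -> patient-frame tip


# ---------------------------------------------------------------------------
# analytic primitives used by the scripts
# ---------------------------------------------------------------------------

def _analytic_surface_distance(spec: AnatomySpec, p: np.ndarray) -> float:
    c = np.asarray(spec.center, dtype=np.float64)
    if spec.shape == "sphere":
        return abs(float(np.linalg.norm(p - c)) - spec.size[0])
    if spec.shape == "tube":
        radius, length = spec.size
        axis = np.asarray(spec.axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        rel = p - c
        h = float(np.dot(rel, axis))
        radial = np.linalg.norm(rel - h * axis)
        hc = np.clip(h, -length / 2, length / 2)
        if abs(h) <= length / 2:
            return abs(radial - radius)
        # beyond the caps: distance to cap disc edge/face
        dh = abs(h) - length / 2
        dr = max(radial - radius, 0.0)
        return float(np.hypot(dh, dr))
    if spec.shape == "box":
        e = np.asarray(spec.size, dtype=np.float64) / 2
        q = np.abs(p - c) - e
        outside = np.linalg.norm(np.maximum(q, 0.0))
        inside = min(float(q.max()), 0.0)
        return abs(outside + inside)
    raise ScriptError(f"unknown shape '{spec.shape}'")


def _contact_point(spec: AnatomySpec, toward: np.ndarray, clearance: float) -> np.ndarray:
    """Point at ``clearance`` mm outside the structure surface, on the side
    facing ``toward``."""
    c = np.asarray(spec.center, dtype=np.float64)
    if spec.shape == "sphere":
        d = toward - c
        d = d / np.linalg.norm(d)
        return c + (spec.size[0] + clearance) * d
    if spec.shape == "tube":
        radius, length = spec.size
        axis = np.asarray(spec.axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        rel = toward - c
        h = np.clip(float(np.dot(rel, axis)), -0.35 * length, 0.35 * length)
        radial = rel - float(np.dot(rel, axis)) * axis
        n = np.linalg.norm(radial)
        if n < 1e-9:
            raise ScriptError(f"approach direction parallel to tube '{spec.name}'")
        return c + h * axis + (radius + clearance) * radial / n
    raise ScriptError(f"contacts on shape '{spec.shape}' are not supported")


def _build_mesh(spec: AnatomySpec):
    if spec.shape == "sphere":
        return icosphere(spec.size[0], spec.subdivisions, center=spec.center, name=spec.name)
    if spec.shape == "tube":
        radius, length = spec.size
        mesh = capped_tube(radius, length, name=spec.name)
        axis = np.asarray(spec.axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, axis)
        s = np.linalg.norm(v)
        if s < 1e-12:
            rot = np.eye(3) if axis[2] > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - float(np.dot(z, axis))) / s**2)
        verts = mesh.vertices @ rot.T + np.asarray(spec.center, dtype=np.float64)
        from .geometry import TriangleMesh

        return TriangleMesh(verts, mesh.faces, name=spec.name)
    if spec.shape == "box":
        from .primitives import box

        return box(spec.size, center=spec.center, name=spec.name)
    raise ScriptError(f"unknown shape '{spec.shape}'")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _tip_path(script: InstrumentScript, scene_by_name: dict[str, AnatomySpec], duration: float | None = None):
    """Piecewise trajectory: rest -> smoothstep approach -> stationary dwell
    -> smoothstep retreat -> rest, per contact."""
    rest = np.asarray(script.rest_position, dtype=np.float64)
    segments = []
    for contact in sorted(script.contacts, key=lambda c: c.t_start):
        if contact.structure not in scene_by_name:
            raise ScriptError(
                f"instrument '{script.name}' contacts unknown structure '{contact.structure}'"
            )
        spec = scene_by_name[contact.structure]
        point = _contact_point(spec, rest, contact.clearance)
        t0 = contact.t_start - TRANSITION_S
        t1 = contact.t_start + contact.dwell + TRANSITION_S
        if t0 < 0:
            raise ScriptError(f"contact at t={contact.t_start} starts before the session")
        if duration is not None and t1 > duration:
            raise ScriptError(
                f"contact at t={contact.t_start} (incl. retreat until {t1:.2f} s) "
                f"exceeds the session duration {duration} s"
            )
        if segments and t0 < segments[-1][1]:
            raise ScriptError(f"overlapping contact segments for instrument '{script.name}'")
        segments.append((t0, t1, contact, point))

    def path(t):
        t = np.asarray(t, dtype=np.float64)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.tile(rest, (len(t), 1))
        for t0, t1, contact, point in segments:
            ts, te = contact.t_start, contact.t_start + contact.dwell
            m = (t >= t0) & (t < ts)
            if m.any():
                u = _smoothstep((t[m] - t0) / TRANSITION_S)
                out[m] = rest + u[:, None] * (point - rest)
            m = (t >= ts) & (t <= te)
            out[m] = point
            m = (t > te) & (t <= t1)
            if m.any():
                u = _smoothstep((t[m] - te) / TRANSITION_S)
                out[m] = point + u[:, None] * (rest - point)
        return out[0] if scalar else out

    return path, segments


def _look_at_pose(eye: np.ndarray, target: np.ndarray, up_hint: np.ndarray) -> RigidTransform:
    """Camera pose (camera-in-parent): +z optical axis toward target, +x
    right, +y down (matching the image convention)."""
    z = target - eye
    z = z / np.linalg.norm(z)
    x = np.cross(up_hint, z)
    n = np.linalg.norm(x)
    if n < 1e-9:
        raise ScriptError("camera up hint parallel to viewing direction")
    x /= n
    y = np.cross(z, x)
    m = np.eye(4)
    m[:3, 0], m[:3, 1], m[:3, 2], m[:3, 3] = x, y, z, eye
    return RigidTransform.from_matrix(m)


def _shaft_rotation(shaft_dir: np.ndarray) -> np.ndarray:
    """Rotation whose +z maps to -shaft_dir so that the handle (array origin)
    sits along ``shaft_dir`` from the tip for a +z tip offset."""
    z = -shaft_dir / np.linalg.norm(shaft_dir)
    tmp = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(tmp, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_session(config: SynthConfig) -> tuple[Session, GroundTruth]:
    """Build a deterministic synthetic session plus its scripted ground truth."""
    scene_by_name = {s.name: s for s in config.scene}
    if len(scene_by_name) != len(config.scene):
        raise ScriptError("duplicate structure names in scene")

    ss = np.random.SeedSequence(config.seed)
    ss_jitter, ss_dropout, ss_reg = ss.spawn(3)
    rng_jitter = np.random.default_rng(ss_jitter)
    rng_dropout = np.random.default_rng(ss_dropout)
    rng_reg = np.random.default_rng(ss_reg)

    n_frames = int(round(config.duration * config.frame_rate))
    clock = FrameClock(np.arange(n_frames) / config.frame_rate, nominal_rate=config.frame_rate)
    n_samples = int(round(config.duration * config.tracking_rate)) + 1
    sample_t = np.arange(n_samples) / config.tracking_rate

    # --- static calibration chain ------------------------------------------
    true_hand_eye = RigidTransform.from_axis_angle([0.2, 0.9, 0.4], 0.35, [5.0, -8.0, 40.0])
    t_tracker_table = RigidTransform.from_axis_angle([0.0, 0.0, 1.0], 0.4, [500.0, 300.0, 1200.0])
    true_registration = RigidTransform.from_axis_angle([0.3, -0.2, 1.0], 0.25, [120.0, -80.0, 60.0])
    t_tracker_patient = compose(t_tracker_table, true_registration)

    # --- camera path (patient frame) ---------------------------------------
    eye0 = np.asarray(config.camera_look_from, dtype=np.float64)
    look_at = np.asarray(config.camera_look_at, dtype=np.float64)
    up_hint = np.array([0.0, 1.0, 0.2])

    def camera_pose_patient(t: float) -> RigidTransform:
        w = 2 * np.pi * t / config.camera_orbit_period
        eye = eye0 + config.camera_orbit_mm * np.array(
            [np.sin(w), 0.5 * np.cos(w) - 0.5, 0.2 * np.sin(0.5 * w)]
        )
        return _look_at_pose(eye, look_at, up_hint)

    # --- frames and edges ---------------------------------------------------
    frames = ["tracker", "table_array", "patient", "scope_array", "camera"]
    for script in config.instruments:
        frames.append(f"{script.name}_array")

    static_edges = [
        StaticEdge("registration", "table_array", "patient", true_registration),
        StaticEdge("hand_eye", "scope_array", "camera", invert(true_hand_eye)),
    ]

    def jitter_pose(pose: RigidTransform, rng) -> RigidTransform:
        if config.noise.jitter_sigma_t == 0.0 and config.noise.jitter_sigma_r == 0.0:
            return pose
        t = pose.translation + rng.normal(0.0, config.noise.jitter_sigma_t or 0.0, 3)
        q = pose.quaternion
        if config.noise.jitter_sigma_r > 0.0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.radians(rng.normal(0.0, config.noise.jitter_sigma_r))
            q = compose(RigidTransform.from_axis_angle(axis, ang), RigidTransform(q, [0, 0, 0])).quaternion
        return RigidTransform(q, t)

    def make_stream(name: str, parent: str, child: str, pose_fn) -> TransformStream:
        qs = np.empty((n_samples, 4))
        tsl = np.empty((n_samples, 3))
        valid = np.ones(n_samples, dtype=bool)
        for i, t in enumerate(sample_t):
            pose = jitter_pose(pose_fn(float(t)), rng_jitter)
            qs[i] = pose.quaternion
            tsl[i] = pose.translation
        if config.noise.dropout_prob > 0.0:
            valid &= rng_dropout.random(n_samples) >= config.noise.dropout_prob
            if not valid.any():
                valid[0] = True
        return TransformStream(name, parent, child, sample_t.copy(), qs, tsl, valid)

    streams = [
        make_stream("table", "tracker", "table_array", lambda t: t_tracker_table),
        make_stream(
            "scope",
            "tracker",
            "scope_array",
            lambda t: compose(
                compose(t_tracker_patient, camera_pose_patient(t)), true_hand_eye
            ),
        ),
    ]

    # --- instruments --------------------------------------------------------
    instruments = []
    tip_offsets: dict[str, np.ndarray] = {}
    tip_paths: dict[str, object] = {}
    truth_events: list[TripletEvent] = []
    for script in config.instruments:
        tip_offset = np.asarray(script.tip_offset, dtype=np.float64)
        tip_offsets[script.name] = tip_offset
        path, segments = _tip_path(script, scene_by_name, config.duration)
        tip_paths[script.name] = path

        # rest position must sit safely outside every contact band
        rest = np.asarray(script.rest_position, dtype=np.float64)
        for spec in config.scene:
            d = _analytic_surface_distance(spec, rest)
            if d <= 7.0:
                raise ScriptError(
                    f"instrument '{script.name}' rests {d:.1f} mm from '{spec.name}' "
                    "(must exceed tau_exit + 2 = 7 mm)"
                )

        # transition segments must stay clear of every *other* structure
        for t0, t1, contact, point in segments:
            for u in np.linspace(0.0, 1.0, 64):
                p = rest + u * (point - rest)
                for spec in config.scene:
                    if spec.name == contact.structure:
                        continue
                    if _analytic_surface_distance(spec, p) <= 7.0:
                        raise ScriptError(
                            f"instrument '{script.name}' transition to '{contact.structure}' "
                            f"passes within 7 mm of '{spec.name}'"
                        )

        r_pa = _shaft_rotation(np.asarray(script.shaft_direction, dtype=np.float64))
        r_ta = t_tracker_patient.rotation_matrix @ r_pa
        q_ta = RigidTransform.from_matrix(
            np.block([[r_ta, np.zeros((3, 1))], [np.zeros((1, 3)), 1.0]])
        ).quaternion

        def pose_fn(t, path=path):
            tip_tracker = t_tracker_patient.apply(path(t))
            return RigidTransform(q_ta, tip_tracker - r_ta @ tip_offset)

        streams.append(make_stream(script.name, "tracker", f"{script.name}_array", pose_fn))
        instruments.append(
            Instrument(
                name=script.name,
                archetype=script.archetype,
                array_frame=f"{script.name}_array",
                tip_offset=tip_offset,
                tool_radius=script.tool_radius,
                verbs=sorted(
                    {v for v in DEFAULT_VERB_TABLE[script.archetype].values() if v != "idle"}
                ),
            )
        )
        for _, _, contact, _ in segments:
            verb = DEFAULT_VERB_TABLE[script.archetype][(True, "static")]
            truth_events.append(
                TripletEvent(
                    instrument=script.name,
                    verb=verb,
                    target=contact.structure,
                    t_start=contact.t_start,
                    t_end=contact.t_start + contact.dwell,
                    mean_confidence=max(0.0, 1.0 - contact.clearance / 3.0),
                    frames=int(round(contact.dwell * config.frame_rate)),
                )
            )
    truth_events.sort(key=lambda e: (e.t_start, e.instrument))

    # --- anatomies ----------------------------------------------------------
    anatomies = []
    spheres = {}
    chord_tols = {}
    for spec in config.scene:
        mesh = _build_mesh(spec)
        anatomies.append(
            Anatomy(
                name=spec.name,
                label_id=spec.label_id,
                frame="patient",
                mesh=mesh,
                mesh_file=f"meshes/{spec.name}.ply",
            )
        )
        if spec.shape == "sphere":
            spheres[spec.name] = (np.asarray(spec.center, dtype=np.float64), spec.size[0])
            chord_tols[spec.name] = sphere_chord_tolerance(mesh, spec.size[0], spec.center)

    session = Session(
        session_id=f"synth-{config.seed}",
        frames=frames,
        static_edges=static_edges,
        streams=streams,
        camera=config.camera,
        camera_frame="camera",
        patient_frame="patient",
        anatomies=anatomies,
        instruments=instruments,
        clock=clock,
    )

    if config.noise.registration_offset > 0.0:
        session = perturb_registration(
            session, config.noise.registration_offset, 0.0, rng=rng_reg
        )

    truth = GroundTruth(
        contact_events=truth_events,
        true_hand_eye=true_hand_eye,
        true_tip_offsets=tip_offsets,
        true_registration=true_registration,
        spheres=spheres,
        chord_tolerances=chord_tols,
        tip_paths=tip_paths,
    )
    return session, truth


def perturb_registration(
    session: Session,
    offset_mm: float,
    offset_deg: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Session:
    """Replace the patient-registration static edge with a perturbed copy:
    a translation of exactly ``offset_mm`` in a seeded random direction plus
    an ``offset_deg`` rotation about a seeded random axis."""
    if offset_mm < 0 or offset_deg < 0:
        raise ValueError("offsets must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if offset_mm == 0.0 and offset_deg == 0.0:
        delta = RigidTransform.identity()
    else:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        delta = RigidTransform.from_axis_angle(axis, np.radians(offset_deg), offset_mm * direction)
    edges = []
    found = False
    for e in session.static_edges:
        if e.name == "registration":
            edges.append(StaticEdge(e.name, e.parent_frame, e.child_frame, compose(delta, e.transform)))
            found = True
        else:
            edges.append(e)
    if not found:
        raise ScriptError("session has no static edge named 'registration'")
    return replace(session, static_edges=edges)


# ---------------------------------------------------------------------------
# analytic sphere silhouette (render oracle)
# ---------------------------------------------------------------------------

def analytic_sphere_silhouette(camera: CameraModel, center, r: float):
    """Exact silhouette of a sphere under a zero-distortion pinhole camera.

    Returns ``(center_px, radius_px, area_px2)``. For on-axis spheres the
    radius is ``f * r / sqrt(z^2 - r^2)``; off-axis the projected cone
    intersects the image plane in an ellipse and ``radius_px`` is the
    geometric mean of its semi-axes (area stays exact).
    """
    if camera.has_distortion:
        raise ValueError("analytic silhouette requires zero distortion")
    c = np.asarray(center, dtype=np.float64).reshape(3)
    d2 = float(c @ c)
    if d2 <= r * r:
        raise ValueError("camera centre inside the sphere")
    if c[2] <= 0:
        raise ValueError("sphere behind the camera")
    # tangency condition for view directions v: (c.v)^2 = cos^2(alpha) |c|^2 |v|^2
    cos2 = 1.0 - r * r / d2
    q = np.outer(c, c) - cos2 * d2 * np.eye(3)
    q2 = q[:2, :2]
    qv = q[:2, 2]
    f = q[2, 2]
    m = np.linalg.solve(q2, -qv)           # ellipse centre, normalized coords
    k = float(f + qv @ m)
    evals, evecs = np.linalg.eigh(q2)
    # (x - m)^T q2 (x - m) = -k with q2 negative definite on the silhouette
    semis = np.sqrt(-k / evals) if k > 0 else np.sqrt(k / -evals)
    area_norm = np.pi * float(semis[0] * semis[1])
    center_px = (camera.fx * m[0] + camera.cx, camera.fy * m[1] + camera.cy)
    radius_px = float(np.sqrt(camera.fx * camera.fy) * np.sqrt(semis[0] * semis[1]))
    area_px = area_norm * camera.fx * camera.fy
    return center_px, radius_px, float(area_px)


# ---------------------------------------------------------------------------
# calibration-closure simulators
# ---------------------------------------------------------------------------

def simulate_pivot_poses(
    tip_offset,
    pivot_point,
    n: int = 100,
    rng: np.random.Generator | None = None,
    jitter_sigma: float = 0.0,
) -> list[RigidTransform]:
    """Array poses pivoting a fixed tip about ``pivot_point`` (tracker frame),
    optionally with isotropic Gaussian translation jitter."""
    rng = rng if rng is not None else np.random.default_rng(0)
    tip = np.asarray(tip_offset, dtype=np.float64)
    pivot = np.asarray(pivot_point, dtype=np.float64)
    poses = []
    for _ in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0.2, 1.2)
        rot = RigidTransform.from_axis_angle(axis, ang)
        t = pivot - rot.rotation_matrix @ tip
        if jitter_sigma > 0.0:
            t = t + rng.normal(0.0, jitter_sigma, 3)
        poses.append(RigidTransform(rot.quaternion, t))
    return poses


def simulate_handeye_motions(
    x: RigidTransform, n: int = 20, rng: np.random.Generator | None = None
):
    """Paired relative motions satisfying A_i X = X B_i exactly."""
    rng = rng if rng is not None else np.random.default_rng(0)
    motions_a, motions_b = [], []
    for _ in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        b = RigidTransform.from_axis_angle(axis, rng.uniform(0.2, 1.0), rng.normal(size=3) * 20.0)
        a = compose(compose(x, b), invert(x))
        motions_a.append(a)
        motions_b.append(b)
    return motions_a, motions_b


# ---------------------------------------------------------------------------
# default demo
# ---------------------------------------------------------------------------

def default_demo_config(duration: float = 60.0, seed: int = 0, noise: NoiseSpec | None = None) -> SynthConfig:
    """60 s, 2 instruments, 3 structures, 6 scripted contacts — one of them
    (grasper on the mesentery) entirely outside the camera frustum."""
    scene = (
        AnatomySpec(name="liver", shape="sphere", size=(25.0,), center=(0.0, 10.0, 10.0), label_id=1),
        AnatomySpec(
            name="mesentery", shape="sphere", size=(20.0,), center=(190.0, 0.0, 20.0), label_id=2
        ),
        AnatomySpec(
            name="ureter",
            shape="tube",
            size=(4.0, 80.0),
            center=(-20.0, -60.0, 0.0),
            axis=(1.0, 0.2, 0.0),
            label_id=3,
        ),
    )
    grasper = InstrumentScript(
        name="grasper",
        archetype="grasper",
        rest_position=(70.0, 55.0, 45.0),
        shaft_direction=(0.35, 0.65, -0.67),
        contacts=(
            ContactSpec("liver", t_start=6.0, dwell=3.0),
            ContactSpec("mesentery", t_start=20.0, dwell=3.0),
            ContactSpec("ureter", t_start=36.0, dwell=2.5),
        ),
    )
    scissors = InstrumentScript(
        name="scissors",
        archetype="scissors",
        rest_position=(-65.0, 50.0, 40.0),
        shaft_direction=(-0.35, 0.65, -0.67),
        contacts=(
            ContactSpec("ureter", t_start=12.0, dwell=2.5),
            ContactSpec("liver", t_start=28.0, dwell=2.0),
            ContactSpec("liver", t_start=44.0, dwell=3.0),
        ),
    )
    # shorter demos keep only the contacts (incl. retreat) that fit
    def fits(c: ContactSpec) -> bool:
        return c.t_start + c.dwell + TRANSITION_S <= duration

    grasper = replace(grasper, contacts=tuple(c for c in grasper.contacts if fits(c)))
    scissors = replace(scissors, contacts=tuple(c for c in scissors.contacts if fits(c)))
    return SynthConfig(
        duration=duration,
        scene=scene,
        instruments=(grasper, scissors),
        noise=noise if noise is not None else NoiseSpec(),
        seed=seed,
    )


def write_truth(truth: GroundTruth, session: Session, path) -> None:
    """Persist ground truth as ``truth/events.json`` + ``truth/calibrations.json``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    from .events import write_triplets_json

    write_triplets_json(truth.contact_events, root / "events.json", session_id=session.session_id)
    calib = {
        "hand_eye": {
            "quaternion": [round(float(v), 9) for v in truth.true_hand_eye.quaternion],
            "translation": [round(float(v), 9) for v in truth.true_hand_eye.translation],
        },
        "registration": {
            "quaternion": [round(float(v), 9) for v in truth.true_registration.quaternion],
            "translation": [round(float(v), 9) for v in truth.true_registration.translation],
        },
        "tip_offsets": {
            k: [round(float(x), 9) for x in v] for k, v in sorted(truth.true_tip_offsets.items())
        },
    }
    (root / "calibrations.json").write_text(json.dumps(calib, sort_keys=True, indent=1) + "\n")
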