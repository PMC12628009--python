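"""Rigid-transform algebra, pose interpolation, and point-mesh queries.

Conventions (package-wide):

* Quaternions are stored ``(w, x, y, z)``, Hamilton convention, and are
  renormalized after every constructor/compose so the unit-norm invariant
  holds to 1e-9.
* A :class:`RigidTransform` acts on a point as ``p' = R @ p + t`` in
  right-handed frames.
* All lengths are millimetres, all times seconds.
* Distances to meshes are unsigned; containment is a separate predicate
  (:func:`point_in_mesh`) because open anatomy meshes have no well-defined
  signed distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateTriangleError,
    EmptyMeshError,
    NotWatertightError,
    OutOfRangeError,
)

__all__ = [
    "RigidTransform",
    "TriangleMesh",
    "compose",
    "invert",
    "interpolate_pose",
    "point_triangle_distance",
    "mesh_distance",
    "point_in_mesh",
]

_QUAT_NORM_TOL = 1e-9


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _matrix_to_quat(m: np.ndarray) -> np.ndarray:
    # Shepperd's method: pick the most stable of the four branches.
    tr = np.trace(m)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    elif m[0, 0] > m[1, 1] and m[0, 0] > m[2, 2]:
        s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
        q = np.array(
            [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        )
    elif m[1, 1] > m[2, 2]:
        s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
        q = np.array(
            [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        )
    else:
        s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
        q = np.array(
            [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
        )
    return q / np.linalg.norm(q)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t``.

    ``quaternion`` is ``(w, x, y, z)``; it is renormalized on construction,
    so downstream code can rely on unit norm to 1e-9.
    """

    quaternion: np.ndarray
    translation: np.ndarray

    def __init__(self, quaternion, translation):
        q = np.asarray(quaternion, dtype=np.float64).reshape(4).copy()
        t = np.asarray(translation, dtype=np.float64).reshape(3).copy()
        n = np.linalg.norm(q)
        if n < 1e-12:
            raise ValueError("zero-norm quaternion")
        q /= n
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(_matrix_to_quat(m[:3, :3]), m[:3, 3])

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        half = 0.5 * angle_rad
        q = np.concatenate(([np.cos(half)], np.sin(half) * axis))
        return cls(q, translation)

    # -- views --------------------------------------------------------------
    @property
    def rotation_matrix(self) -> np.ndarray:
        return _quat_to_matrix(self.quaternion)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix
        m[:3, 3] = self.translation
        return m

    # -- algebra ------------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Transform one point (3,) or many points (N, 3)."""
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation_matrix.T + self.translation

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians, in [0, pi]."""
        w = min(1.0, abs(float(self.quaternion[0])))
        return 2.0 * np.arccos(w)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        qa, qb = self.quaternion, other.quaternion
        if np.dot(qa, qb) < 0:
            qb = -qb
        return bool(
            np.allclose(qa, qb, atol=atol) and np.allclose(self.translation, other.translation, atol=atol)
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a ∘ b``: ``compose(a, b).apply(p) == a.apply(b.apply(p))``."""
    q = _quat_mul(a.quaternion, b.quaternion)
    t = a.apply(b.translation)
    return RigidTransform(q, t)


def invert(t: RigidTransform) -> RigidTransform:
    q_inv = t.quaternion * np.array([1.0, -1.0, -1.0, -1.0])
    r_inv = _quat_to_matrix(q_inv)
    return RigidTransform(q_inv, -(r_inv @ t.translation))


def interpolate_pose(
    t0: float, p0: RigidTransform, t1: float, p1: RigidTransform, t: float
) -> RigidTransform:
    """Linear translation / shortest-arc SLERP rotation between two stamps.

    No extrapolation: ``t`` must lie in ``[t0, t1]``.
    """
    if not t0 < t1:
        raise OutOfRangeError(f"require t0 < t1, got {t0} >= {t1}")
    if t < t0 or t > t1:
        raise OutOfRangeError(f"t={t} outside [{t0}, {t1}]")
    if t == t0:
        return p0
    if t == t1:
        return p1
    alpha = (t - t0) / (t1 - t0)
    q0, q1 = p0.quaternion, p1.quaternion.copy()
    dot = float(np.dot(q0, q1))
    if dot < 0.0:  # shortest arc
        q1 = -q1
        dot = -dot
    if dot > 1.0 - 1e-12:
        q = (1 - alpha) * q0 + alpha * q1  # nearly parallel: nlerp is exact enough
    else:
        theta = np.arccos(dot)
        q = (np.sin((1 - alpha) * theta) * q0 + np.sin(alpha * theta) * q1) / np.sin(theta)
    trans = (1 - alpha) * p0.translation + alpha * p1.translation
    return RigidTransform(q, trans)


# ---------------------------------------------------------------------------
# Triangle meshes
# ---------------------------------------------------------------------------

_MIN_FACE_AREA = 1e-12  # mm^2


class TriangleMesh:
    """Indexed triangle mesh in millimetres.

    Face indices are validated at construction; faces with area below
    1e-12 mm^2 are rejected. Acceleration structures (vertex k-d tree,
    face bounding boxes) are built lazily and never change results.
    """

    def __init__(self, vertices, faces, name: str = ""):
        self.vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        self.name = name
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise IndexError(f"face index out of range for mesh '{name}' ({n} vertices)")
        if self.faces.size:
            areas = self.face_areas()
            if np.any(areas < _MIN_FACE_AREA):
                bad = int(np.argmin(areas))
                raise DegenerateTriangleError(
                    f"mesh '{name}': face {bad} has area {areas[bad]:.3e} mm^2"
                )
        self._kdtree = None
        self._face_aabb = None
        self._watertight = None

    # -- derived quantities --------------------------------------------------
    def triangle_corners(self):
        v, f = self.vertices, self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def is_watertight(self) -> bool:
        """Closed and consistently oriented: every undirected edge is shared by
        exactly two faces and every directed edge appears exactly once."""
        if self._watertight is None:
            if not self.faces.size:
                self._watertight = False
            else:
                e = np.vstack(
                    [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
                )
                directed = {}
                ok = True
                for u, v in e:
                    key = (int(u), int(v))
                    if key in directed:
                        ok = False
                        break
                    directed[key] = True
                if ok:
                    for u, v in directed:
                        if (v, u) not in directed:
                            ok = False
                            break
                self._watertight = ok
        return self._watertight

    def _accel(self):
        if self._kdtree is None:
            self._kdtree = cKDTree(self.vertices)
            a, b, c = self.triangle_corners()
            stacked = np.stack([a, b, c])
            self._face_aabb = (stacked.min(axis=0), stacked.max(axis=0))
        return self._kdtree, self._face_aabb

    def transformed(self, t: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(t.apply(self.vertices), self.faces, name=self.name)

    def __repr__(self):
        return f"TriangleMesh(name={self.name!r}, V={len(self.vertices)}, F={len(self.faces)})"


def _clamp01(x):
    return np.clip(x, 0.0, 1.0)


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest points on triangles (a,b,c) to point p, vectorized.

    Region classification after Eberly's point/triangle distance; all
    denominators are positive for non-degenerate triangles.
    Returns (squared distances, closest points).
    """
    e0 = b - a
    e1 = c - a
    d0 = a - p
    aa = np.einsum("ij,ij->i", e0, e0)
    bb = np.einsum("ij,ij->i", e0, e1)
    cc = np.einsum("ij,ij->i", e1, e1)
    dd = np.einsum("ij,ij->i", e0, d0)
    ee = np.einsum("ij,ij->i", e1, d0)
    det = aa * cc - bb * bb
    det = np.maximum(det, 1e-300)
    s = bb * ee - cc * dd
    t = bb * dd - aa * ee

    # region candidates
    s_out = np.empty_like(s)
    t_out = np.empty_like(t)

    inside = (s + t <= det) & (s >= 0) & (t >= 0)
    s_out[inside] = s[inside] / det[inside]
    t_out[inside] = t[inside] / det[inside]

    denom_ac = aa - 2 * bb + cc  # |e0 - e1|^2 > 0

    # region 3/5-ish: edges from vertex a
    m = (s + t <= det) & (s < 0) & (t >= 0)  # region 3: edge e1 (s=0)
    t_out[m] = _clamp01(-ee[m] / cc[m])
    s_out[m] = 0.0

    m = (s + t <= det) & (s >= 0) & (t < 0)  # region 5: edge e0 (t=0)
    s_out[m] = _clamp01(-dd[m] / aa[m])
    t_out[m] = 0.0

    m = (s + t <= det) & (s < 0) & (t < 0)  # region 4: vertex a corner
    pick_e0 = dd < 0
    m0 = m & pick_e0
    s_out[m0] = _clamp01(-dd[m0] / aa[m0])
    t_out[m0] = 0.0
    m1 = m & ~pick_e0
    s_out[m1] = 0.0
    t_out[m1] = _clamp01(-ee[m1] / cc[m1])

    far = s + t > det

    m = far & (s < 0)  # region 2
    tmp0 = bb + dd
    tmp1 = cc + ee
    use_edge = tmp1 > tmp0
    m0 = m & use_edge
    s_out[m0] = _clamp01((tmp1[m0] - tmp0[m0]) / denom_ac[m0])
    t_out[m0] = 1.0 - s_out[m0]
    m1 = m & ~use_edge
    s_out[m1] = 0.0
    t_out[m1] = _clamp01(-ee[m1] / cc[m1])

    m = far & (s >= 0) & (t < 0)  # region 6
    tmp0 = bb + ee
    tmp1 = aa + dd
    use_edge = tmp1 > tmp0
    m0 = m & use_edge
    t_out[m0] = _clamp01((tmp1[m0] - tmp0[m0]) / denom_ac[m0])
    s_out[m0] = 1.0 - t_out[m0]
    m1 = m & ~use_edge
    t_out[m1] = 0.0
    s_out[m1] = _clamp01(-dd[m1] / aa[m1])

    m = far & (s >= 0) & (t >= 0)  # region 1: hypotenuse edge
    numer = cc + ee - bb - dd
    s_out[m] = _clamp01(numer[m] / denom_ac[m])
    t_out[m] = 1.0 - s_out[m]

    closest = a + s_out[:, None] * e0 + t_out[:, None] * e1
    diff = closest - p
    return np.einsum("ij,ij->i", diff, diff), closest


def point_triangle_distance(p, a, b, c):
    """Exact unsigned distance from point ``p`` to triangle ``(a, b, c)``.

    Returns ``(distance_mm, closest_point)``.
    """
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64).reshape(1, 3)
    b = np.asarray(b, dtype=np.float64).reshape(1, 3)
    c = np.asarray(c, dtype=np.float64).reshape(1, 3)
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
    if area < _MIN_FACE_AREA:
        raise DegenerateTriangleError(f"triangle area {area:.3e} mm^2")
    d2, closest = _closest_on_triangles(p, a, b, c)
    return float(np.sqrt(d2[0])), closest[0]


def mesh_distance(p, mesh: TriangleMesh, accelerated: bool = True):
    """Minimum unsigned distance from ``p`` to ``mesh``.

    Returns ``(distance_mm, face_index, closest_point)``. The accelerated
    path prunes faces whose bounding box is farther than the nearest-vertex
    upper bound; by construction its result is identical to exhaustive
    search (ties resolved to the lowest face index in both paths).
    """
    if not mesh.faces.size:
        raise EmptyMeshError(f"mesh '{mesh.name}' has no faces")
    p = np.asarray(p, dtype=np.float64).reshape(3)
    a, b, c = mesh.triangle_corners()
    if accelerated:
        kdtree, (lo, hi) = mesh._accel()
        d_ub, _ = kdtree.query(p)
        # distance from p to each face AABB; only faces that can beat the
        # nearest-vertex upper bound need an exact test
        gap = np.maximum(np.maximum(lo - p, p - hi), 0.0)
        aabb_d2 = np.einsum("ij,ij->i", gap, gap)
        cand = np.flatnonzero(aabb_d2 <= d_ub * d_ub + 1e-12)
        d2, closest = _closest_on_triangles(p, a[cand], b[cand], c[cand])
        k = int(np.argmin(d2))
        return float(np.sqrt(d2[k])), int(cand[k]), closest[k]
    d2, closest = _closest_on_triangles(p, a, b, c)
    k = int(np.argmin(d2))
    return float(np.sqrt(d2[k])), k, closest[k]


def _ray_hits(origin, direction, a, b, c):
    """Möller–Trumbore over all faces. Returns (#crossings, ambiguous)."""
    eps_par = 1e-12
    eps_bary = 1e-10
    e1 = b - a
    e2 = c - a
    h = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, h)
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    nonpar = np.abs(det) > eps_par * np.maximum(scale, 1e-30)
    inv = np.where(nonpar, 1.0 / np.where(nonpar, det, 1.0), 0.0)
    s = origin[None, :] - a
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("ij,j->i", q, direction) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    w = 1.0 - u - v
    hit = nonpar & (u >= -eps_bary) & (v >= -eps_bary) & (w >= -eps_bary) & (t > eps_bary)
    near_boundary = hit & (
        (np.abs(u) < eps_bary) | (np.abs(v) < eps_bary) | (np.abs(w) < eps_bary)
    )
    ambiguous = bool(near_boundary.any()) or bool(np.any(hit & (t < 1e-9)))
    return int(np.count_nonzero(hit)), ambiguous


def point_in_mesh(p, mesh: TriangleMesh) -> bool:
    """Ray-crossing parity containment test; requires a watertight mesh.

    Uses a fixed ray direction with deterministic perturbation retries when
    the ray grazes a vertex or edge. Points lying on the surface are not
    strictly inside and return ``False``.
    """
    if not mesh.is_watertight:
        raise NotWatertightError(
            f"mesh '{mesh.name}' is not watertight; containment is unsupported"
        )
    p = np.asarray(p, dtype=np.float64).reshape(3)
    d, _, _ = mesh_distance(p, mesh)
    if d < 1e-9:
        return False
    a, b, c = mesh.triangle_corners()
    base = np.array([0.577350269189626, 0.577350269189626, 0.577350269189626])
    for k in range(16):
        if k == 0:
            direction = base
        else:  # deterministic perturbation schedule
            tweak = np.array(
                [np.cos(0.7 * k), np.sin(1.3 * k + 0.5), np.cos(2.1 * k + 1.0)]
            )
            direction = base + 1e-3 * k * tweak
            direction /= np.linalg.norm(direction)
        crossings, ambiguous = _ray_hits(p, direction, a, b, c)
        if not ambiguous:
            return crossings % 2 == 1
    raise OutOfRangeError("containment test failed to find an unambiguous ray")
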