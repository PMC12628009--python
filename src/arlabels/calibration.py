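"""Calibration solvers for a tracked-surgery setup.

* :func:`pivot_calibrate` — tool-tip offset from poses pivoting about a fixed
  point (stacked linear least squares).
* :func:`hand_eye_calibrate` — AX = XB from paired relative motions; rotation
  from a linear quaternion system, translation by least squares afterwards.
* :func:`register_points` — closed-form rigid point-set registration (SVD)
  with a reflection guard; rigid stand-in for patient registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConditioningError, DegenerateConfigurationError, UnderdeterminedError
from .geometry import RigidTransform, _quat_mul

__all__ = [
    "PivotResult",
    "HandEyeResult",
    "RegistrationResult",
    "pivot_calibrate",
    "hand_eye_calibrate",
    "register_points",
]

PIVOT_MAX_CONDITION = 1e6
HANDEYE_MIN_AXIS_ANGLE_DEG = 5.0


@dataclass(frozen=True)
class PivotResult:
    tip_offset: np.ndarray          # mm, in the instrument-array frame
    pivot_point: np.ndarray         # mm, in the tracker frame
    rms_residual: float             # mm
    condition_number: float


@dataclass(frozen=True)
class HandEyeResult:
    x: RigidTransform               # array frame -> camera optical frame
    rotation_residual: float        # rad, rms over pairs
    translation_residual: float     # mm, rms over pairs


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    fiducial_registration_error: float  # mm, rms


def pivot_calibrate(poses: list[RigidTransform]) -> PivotResult:
    """Solve ``R_i @ tip + t_i = pivot`` for all poses in the least-squares sense.

    ``poses`` map the instrument-array frame into the tracker frame. Requires
    at least 3 poses with rotational diversity; a stacked-system condition
    number above ``PIVOT_MAX_CONDITION`` raises :class:`ConditioningError`.
    """
    if len(poses) < 3:
        raise UnderdeterminedError(f"pivot calibration needs >= 3 poses, got {len(poses)}")
    n = len(poses)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, p in enumerate(poses):
        A[3 * i : 3 * i + 3, :3] = p.rotation_matrix
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -p.translation
    sv = np.linalg.svd(A, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    if cond > PIVOT_MAX_CONDITION:
        raise ConditioningError(
            f"pivot system ill-conditioned (condition number {cond:.3g}); "
            "poses lack rotational diversity",
            condition_number=cond,
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    tip, pivot = x[:3], x[3:]
    res = np.array([p.rotation_matrix @ tip + p.translation - pivot for p in poses])
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return PivotResult(tip_offset=tip, pivot_point=pivot, rms_residual=rms, condition_number=cond)


def _quat_left(q):
    w, x, y, z = q
    return np.array(
        [[w, -x, -y, -z], [x, w, -z, y], [y, z, w, -x], [z, -y, x, w]]
    )


def _quat_right(q):
    w, x, y, z = q
    return np.array(
        [[w, -x, -y, -z], [x, w, z, -y], [y, -z, w, x], [z, y, -x, w]]
    )


def _canonical(q):
    return q if q[0] >= 0 else -q


def hand_eye_calibrate(
    motions_a: list[RigidTransform], motions_b: list[RigidTransform]
) -> HandEyeResult:
    """Solve AX = XB from paired relative motions.

    ``motions_a`` are relative motions of the tracked array, ``motions_b``
    the matching relative motions of the camera. Needs >= 2 pairs whose
    rotation axes are separated by at least ``HANDEYE_MIN_AXIS_ANGLE_DEG``.
    """
    if len(motions_a) != len(motions_b):
        raise ValueError("motion lists must be paired")
    if len(motions_a) < 2:
        raise UnderdeterminedError("hand-eye needs >= 2 motion pairs")

    axes = []
    for m in motions_a:
        q = _canonical(m.quaternion)
        v = q[1:]
        nv = np.linalg.norm(v)
        if nv > 1e-9:
            axes.append(v / nv)
    max_angle = 0.0
    for i in range(len(axes)):
        for j in range(i + 1, len(axes)):
            cosang = np.clip(abs(np.dot(axes[i], axes[j])), 0.0, 1.0)
            max_angle = max(max_angle, np.degrees(np.arccos(cosang)))
    if len(axes) < 2 or max_angle < HANDEYE_MIN_AXIS_ANGLE_DEG:
        raise UnderdeterminedError(
            "hand-eye motions under-determined: rotation axes are (near-)parallel "
            f"(max separation {max_angle:.2f} deg)"
        )

    # rotation: stack [L(q_a) - R(q_b)] q_x = 0, take the least singular vector
    M = np.vstack(
        [
            _quat_left(_canonical(a.quaternion)) - _quat_right(_canonical(b.quaternion))
            for a, b in zip(motions_a, motions_b)
        ]
    )
    _, _, vt = np.linalg.svd(M)
    qx = vt[-1]
    x_rot = RigidTransform(qx, np.zeros(3))
    rx = x_rot.rotation_matrix

    # translation: (R_a - I) t_x = R_x t_b - t_a
    A = np.vstack([a.rotation_matrix - np.eye(3) for a in motions_a])
    rhs = np.concatenate([rx @ b.translation - a.translation for a, b in zip(motions_a, motions_b)])
    tx, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    x = RigidTransform(qx, tx)

    rot_res = []
    trans_res = []
    for a, b in zip(motions_a, motions_b):
        lhs = _quat_mul(a.quaternion, x.quaternion)
        rhs_q = _quat_mul(x.quaternion, b.quaternion)
        # relative rotation angle via atan2 (precise for small angles)
        dq = _quat_mul(lhs, rhs_q * np.array([1.0, -1.0, -1.0, -1.0]))
        rot_res.append(2.0 * np.arctan2(np.linalg.norm(dq[1:]), abs(float(dq[0]))))
        trans_res.append((a.rotation_matrix - np.eye(3)) @ tx - (rx @ b.translation - a.translation))
    rot_rms = float(np.sqrt(np.mean(np.square(rot_res))))
    trans_rms = float(np.sqrt(np.mean(np.sum(np.square(trans_res), axis=1))))
    return HandEyeResult(x=x, rotation_residual=rot_rms, translation_residual=trans_rms)


def register_points(source: np.ndarray, target: np.ndarray) -> RegistrationResult:
    """Closed-form rigid registration mapping ``source`` onto ``target``.

    Kabsch/Arun SVD solution with sign correction of the smallest singular
    direction, so the rotation is always proper (det +1), never a reflection.
    """
    src = np.asarray(source, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target, dtype=np.float64).reshape(-1, 3)
    if src.shape != tgt.shape or len(src) < 3:
        raise UnderdeterminedError("registration needs >= 3 paired points")
    sc = src - src.mean(axis=0)
    # collinearity check: second-largest spread must be non-negligible
    spread = np.linalg.svd(sc, compute_uv=False)
    if spread[1] < 1e-9 * max(spread[0], 1.0):
        raise DegenerateConfigurationError("source points are (near-)collinear")
    tc = tgt - tgt.mean(axis=0)
    h = sc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = tgt.mean(axis=0) - r @ src.mean(axis=0)
    transform = RigidTransform.from_matrix(np.block([[r, t[:, None]], [np.zeros((1, 3)), 1.0]]))
    fre = float(np.sqrt(np.mean(np.sum((transform.apply(src) - tgt) ** 2, axis=1))))
    return RegistrationResult(transform=transform, fiducial_registration_error=fre)
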