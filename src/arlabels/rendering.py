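"""Per-frame raster annotations: label maps, depth maps, instrument masks,
chromadepth images, and visibility classification.

Rasterization conventions (chosen for bit-exact reproducibility):

* image origin top-left, ``u`` right, ``v`` down, pixel centres at integer
  coordinates;
* a pixel is covered when its centre lies inside the projected triangle,
  with a fixed top-left rule for centres exactly on an edge;
* software z-buffer, nearest surface wins; depth is interpolated
  perspective-correctly (linear in 1/z) and stored as float32 millimetres
  along camera +Z, 0 meaning empty;
* triangles with any vertex at ``z <= z_near`` (0.1 mm) are clipped;
* lens distortion is applied to (subdivided) vertices, not per-pixel: edges
  longer than ``EDGE_SUBDIV`` pixels after projection are midpoint-split
  first so the straight-edge approximation error stays bounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import RigidTransform, TriangleMesh
from .primitives import capsule

__all__ = [
    "CameraModel",
    "LabelMap",
    "DepthMap",
    "InstrumentMask",
    "Visibility",
    "VisibilityState",
    "project_point",
    "render_label_map",
    "render_instrument_masks",
    "visibility",
    "render_chromadepth",
]

Z_NEAR = 0.1           # mm
EDGE_SUBDIV = 16.0     # px
OCCLUSION_TOL = 1.0    # mm


@dataclass(frozen=True)
class CameraModel:
    """Distorted pinhole camera (OpenCV-style radial/tangential model)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("image size must be >= 1 px")

    @property
    def has_distortion(self) -> bool:
        return any((self.k1, self.k2, self.p1, self.p2, self.k3))

    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2**2 + self.k3 * r2**3
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def project(self, points_cam: np.ndarray):
        """Project (N, 3) camera-frame points. Returns (uv (N, 2), behind (N,))
        where ``behind`` marks points with z <= Z_NEAR (their uv is NaN)."""
        p = np.asarray(points_cam, dtype=np.float64).reshape(-1, 3)
        z = p[:, 2]
        behind = z <= Z_NEAR
        zsafe = np.where(behind, 1.0, z)
        xy = p[:, :2] / zsafe[:, None]
        xy = self.distort_normalized(xy)
        uv = np.empty_like(xy)
        uv[:, 0] = self.fx * xy[:, 0] + self.cx
        uv[:, 1] = self.fy * xy[:, 1] + self.cy
        uv[behind] = np.nan
        return uv, behind

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
            "k1": self.k1, "k2": self.k2, "p1": self.p1, "p2": self.p2, "k3": self.k3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(**{k: (int(v) if k in ("width", "height") else float(v)) for k, v in d.items()})


def project_point(camera: CameraModel, p):
    """Project a single camera-frame point. Returns ``(u, v)`` or ``None``
    when the point is at or behind the near plane."""
    uv, behind = camera.project(np.asarray(p, dtype=np.float64).reshape(1, 3))
    if behind[0]:
        return None
    return float(uv[0, 0]), float(uv[0, 1])


@dataclass
class LabelMap:
    pixels: np.ndarray                # (h, w) uint8, 0 = background
    legend: dict[int, str]
    t: float = 0.0
    valid: bool = True


@dataclass
class DepthMap:
    pixels: np.ndarray                # (h, w) float32 mm, 0 = empty


@dataclass
class InstrumentMask:
    pixels: np.ndarray                # (h, w) bool
    valid: bool = True


class VisibilityState(str, Enum):
    ON_SCREEN = "on_screen"
    OFF_SCREEN = "off_screen"
    BEHIND_CAMERA = "behind_camera"


@dataclass(frozen=True)
class Visibility:
    state: VisibilityState
    occluded: bool | None = None      # defined only when on_screen


# ---------------------------------------------------------------------------
# rasterization core
# ---------------------------------------------------------------------------

def _subdivide_for_distortion(camera: CameraModel, tris_cam: np.ndarray, max_depth: int = 4):
    """Midpoint-split triangles (in camera space) until their pinhole-projected
    edges are shorter than EDGE_SUBDIV px. Only called when distortion is on."""
    out = []
    stack = [(t, 0) for t in tris_cam]
    f = max(camera.fx, camera.fy)
    while stack:
        tri, depth = stack.pop()
        if depth >= max_depth:
            out.append(tri)
            continue
        uv = tri[:, :2] / tri[:, 2:3] * f
        e = np.linalg.norm(uv - np.roll(uv, -1, axis=0), axis=1)
        if e.max() <= EDGE_SUBDIV:
            out.append(tri)
            continue
        a, b, c = tri
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        stack += [
            (np.array([a, ab, ca]), depth + 1),
            (np.array([ab, b, bc]), depth + 1),
            (np.array([ca, bc, c]), depth + 1),
            (np.array([ab, bc, ca]), depth + 1),
        ]
    return np.array(out)


def _rasterize_mesh(camera: CameraModel, verts_cam: np.ndarray, faces: np.ndarray,
                    depth_buf: np.ndarray, write_value, value_buf=None):
    """Z-buffer rasterization of one mesh into (value_buf, depth_buf) in place."""
    h, w = depth_buf.shape
    tz = verts_cam[faces][:, :, 2]
    keep = np.all(tz > Z_NEAR, axis=1)  # near-plane clip: drop touching triangles
    tris = verts_cam[faces[keep]]
    if tris.size == 0:
        return
    if camera.has_distortion:
        tris = _subdivide_for_distortion(camera, tris)
    flat = tris.reshape(-1, 3)
    uv, _ = camera.project(flat)
    uv = uv.reshape(-1, 3, 2)
    z = tris[:, :, 2]

    # cull triangles entirely outside the image
    lo = uv.min(axis=1)
    hi = uv.max(axis=1)
    on = (hi[:, 0] >= 0) & (hi[:, 1] >= 0) & (lo[:, 0] <= w - 1) & (lo[:, 1] <= h - 1)
    uv, z, lo, hi = uv[on], z[on], lo[on], hi[on]

    for k in range(len(uv)):
        x0, y0 = uv[k, 0]
        x1, y1 = uv[k, 1]
        x2, y2 = uv[k, 2]
        area = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
        if area == 0.0:
            continue
        if area < 0:  # orient so interior edge functions are positive
            x1, y1, x2, y2 = x2, y2, x1, y1
            z1, z2 = z[k, 2], z[k, 1]
            z0 = z[k, 0]
            area = -area
        else:
            z0, z1, z2 = z[k]
        umin = max(int(np.ceil(min(x0, x1, x2))), 0)
        umax = min(int(np.floor(max(x0, x1, x2))), w - 1)
        vmin = max(int(np.ceil(min(y0, y1, y2))), 0)
        vmax = min(int(np.floor(max(y0, y1, y2))), h - 1)
        if umin > umax or vmin > vmax:
            continue
        us = np.arange(umin, umax + 1, dtype=np.float64)
        vs = np.arange(vmin, vmax + 1, dtype=np.float64)
        pu, pv = np.meshgrid(us, vs)

        cov = None
        lams = []
        for (ax, ay, bx, by) in ((x0, y0, x1, y1), (x1, y1, x2, y2), (x2, y2, x0, y0)):
            dx, dy = bx - ax, by - ay
            e = dx * (pv - ay) - dy * (pu - ax)
            # top-left fill rule for centres exactly on an edge
            edge_in = (e > 0) | ((e == 0) & ((dy < 0) | ((dy == 0) & (dx < 0))))
            cov = edge_in if cov is None else (cov & edge_in)
            lams.append(e)
        if not cov.any():
            continue
        # barycentric weights: edge function opposite each vertex
        l0 = lams[1] / area
        l1 = lams[2] / area
        l2 = lams[0] / area
        zpix = 1.0 / (l0 / z0 + l1 / z1 + l2 / z2)
        sub_d = depth_buf[vmin : vmax + 1, umin : umax + 1]
        upd = cov & ((sub_d == 0.0) | (zpix < sub_d))
        if not upd.any():
            continue
        sub_d[upd] = zpix[upd].astype(depth_buf.dtype)
        if value_buf is not None:
            value_buf[vmin : vmax + 1, umin : umax + 1][upd] = write_value


def render_label_map(camera: CameraModel, posed_meshes, t: float = 0.0) -> tuple[LabelMap, DepthMap]:
    """Render ``posed_meshes`` — an iterable of
    ``(TriangleMesh, RigidTransform mesh->camera, label_id)`` — into a
    semantic label map plus depth map. Deterministic: identical scenes give
    byte-identical rasters."""
    h, w = camera.height, camera.width
    labels = np.zeros((h, w), dtype=np.uint8)
    depth = np.zeros((h, w), dtype=np.float32)
    legend: dict[int, str] = {}
    for mesh, pose, label_id in posed_meshes:
        if not (1 <= int(label_id) <= 255):
            raise ValueError(f"label_id {label_id} outside [1, 255]")
        legend[int(label_id)] = mesh.name
        verts_cam = pose.apply(mesh.vertices)
        _rasterize_mesh(camera, verts_cam, mesh.faces, depth, np.uint8(label_id), labels)
    return LabelMap(pixels=labels, legend=legend, t=t), DepthMap(pixels=depth)


def instrument_capsule(tip_cam: np.ndarray, entry_cam: np.ndarray, tool_radius: float,
                       max_length: float = 150.0) -> TriangleMesh:
    """Capsule proxy for an untracked shaft: tip toward the handle/entry
    direction, truncated at ``max_length`` mm."""
    tip = np.asarray(tip_cam, dtype=np.float64)
    entry = np.asarray(entry_cam, dtype=np.float64)
    d = entry - tip
    n = np.linalg.norm(d)
    if n > max_length:
        entry = tip + d / n * max_length
    return capsule(tip, entry, tool_radius, name="instrument")


def render_instrument_masks(camera: CameraModel, instruments, depth: DepthMap,
                            amodal: bool = False) -> dict[str, InstrumentMask]:
    """Render per-instrument binary masks.

    ``instruments`` is an iterable of dicts with keys ``name``, ``valid``,
    ``tip_cam``, ``entry_cam``, ``tool_radius`` and optionally
    ``shaft_mesh`` + ``shaft_pose`` (mesh->camera). With ``amodal=False``
    pixels where the anatomy depth map is strictly nearer are removed;
    ``amodal=True`` keeps the full silhouette.
    """
    h, w = camera.height, camera.width
    out: dict[str, InstrumentMask] = {}
    for inst in instruments:
        name = inst["name"]
        if not inst.get("valid", True):
            out[name] = InstrumentMask(np.zeros((h, w), dtype=bool), valid=False)
            continue
        if inst.get("shaft_mesh") is not None:
            mesh = inst["shaft_mesh"]
            verts_cam = inst["shaft_pose"].apply(mesh.vertices)
            faces = mesh.faces
        else:
            mesh = instrument_capsule(inst["tip_cam"], inst["entry_cam"], inst["tool_radius"])
            verts_cam = mesh.vertices
            faces = mesh.faces
        inst_depth = np.zeros((h, w), dtype=np.float32)
        _rasterize_mesh(camera, verts_cam, faces, inst_depth, None, None)
        mask = inst_depth > 0
        if not amodal:
            occluding = (depth.pixels > 0) & (depth.pixels < inst_depth)
            mask &= ~occluding
        out[name] = InstrumentMask(mask, valid=True)
    return out


def visibility(camera: CameraModel, p, depth: DepthMap | None = None,
               tol: float = OCCLUSION_TOL) -> Visibility:
    """Classify a camera-frame point as on/off-screen/behind-camera; when
    on-screen, flag occlusion by comparing against the anatomy depth map."""
    p = np.asarray(p, dtype=np.float64).reshape(3)
    if p[2] <= Z_NEAR:
        return Visibility(VisibilityState.BEHIND_CAMERA)
    uv, _ = camera.project(p.reshape(1, 3))
    u, v = uv[0]
    if not (0 <= u <= camera.width - 1 and 0 <= v <= camera.height - 1):
        return Visibility(VisibilityState.OFF_SCREEN)
    occluded = False
    if depth is not None:
        d = float(depth.pixels[int(round(v)), int(round(u))])
        occluded = d > 0 and p[2] > d + tol
    return Visibility(VisibilityState.ON_SCREEN, occluded=occluded)


def render_chromadepth(depth: DepthMap, z_min: float, z_max: float) -> np.ndarray:
    """Depth-to-colour ramp: HSV hue from 0 deg (red, near) to 240 deg
    (blue, far), linear in depth over [z_min, z_max] and clamped; background
    stays black. Returns an (h, w, 3) uint8 image."""
    if not z_min < z_max:
        raise ValueError("z_min must be < z_max")
    z = depth.pixels.astype(np.float64)
    frac = np.clip((z - z_min) / (z_max - z_min), 0.0, 1.0)
    hue = 240.0 * frac / 60.0  # sector index in [0, 4]
    i = np.floor(hue).astype(int)
    f = hue - i
    r = np.select([i == 0, i == 1, i <= 3], [1.0, 1.0 - f, 0.0], default=0.0)
    g = np.select([i == 0, i == 1, i == 2, i == 3], [f, 1.0, 1.0, 1.0 - f], default=0.0)
    b = np.select([i <= 1, i == 2, i >= 3], [0.0, f, 1.0], default=0.0)
    rgb = np.stack([r, g, b], axis=-1)
    rgb[z == 0] = 0.0
    return np.round(rgb * 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# raster file I/O
# ---------------------------------------------------------------------------

DEPTH_PNG_SCALE = 10.0  # stored units are 0.1 mm


def save_label_map(label_map: LabelMap, path) -> None:
    """8-bit single-channel PNG plus a sidecar JSON legend."""
    path = Path(path)
    Image.fromarray(label_map.pixels, mode="L").save(path, format="PNG")
    sidecar = path.with_suffix(".json")
    payload = {
        "legend": {str(k): v for k, v in sorted(label_map.legend.items())},
        "t": round(float(label_map.t), 9),
        "valid": bool(label_map.valid),
    }
    sidecar.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def load_label_map(path) -> LabelMap:
    path = Path(path)
    pixels = np.asarray(Image.open(path), dtype=np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    return LabelMap(pixels=pixels, legend=legend, t=meta["t"], valid=meta["valid"])


def save_depth_map(depth: DepthMap, path, raw: bool = False) -> None:
    """16-bit PNG in 0.1 mm units by default; ``raw=True`` stores float32 .npy."""
    path = Path(path)
    if raw:
        np.save(path, depth.pixels)
        return
    q = np.clip(np.round(depth.pixels * DEPTH_PNG_SCALE), 0, 65535).astype(np.uint16)
    Image.fromarray(q).save(path, format="PNG")


def save_mask(mask: InstrumentMask, path) -> None:
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(path, format="PNG")
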