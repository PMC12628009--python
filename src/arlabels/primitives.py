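"""Procedural mesh primitives used by the synthetic scene and the renderer."""

from __future__ import annotations

import numpy as np

from .geometry import TriangleMesh

__all__ = ["icosphere", "box", "capped_tube", "capsule"]


def icosphere(radius: float, subdivisions: int = 4, center=(0.0, 0.0, 0.0), name: str = "") -> TriangleMesh:
    """Subdivided icosahedron with vertices on the sphere (inscribed mesh).

    Chord tolerance (max deviation of the surface from the true sphere) is
    ``radius * (1 - cos(theta/2))`` with ``theta`` the largest edge arc; see
    :func:`sphere_chord_tolerance`.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = np.array(verts[i]) + np.array(verts[j])
            m /= np.linalg.norm(m)
            verts.append(tuple(m))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for i, j, k in faces:
            a = midpoint(i, j)
            b = midpoint(j, k)
            c = midpoint(k, i)
            new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
        faces = new_faces
    v = np.array(verts) * radius + np.asarray(center, dtype=np.float64)
    return TriangleMesh(v, np.array(faces, dtype=np.int64), name=name)


def sphere_chord_tolerance(mesh: TriangleMesh, radius: float, center) -> float:
    """Max radial sag of an inscribed sphere mesh, computed from the mesh itself."""
    a, b, c = mesh.triangle_corners()
    face_centers = (a + b + c) / 3.0
    r_min = np.linalg.norm(face_centers - np.asarray(center), axis=1).min()
    return float(radius - r_min)


def box(extents, center=(0.0, 0.0, 0.0), name: str = "") -> TriangleMesh:
    """Axis-aligned box; ``extents`` are full side lengths (mm)."""
    e = np.asarray(extents, dtype=np.float64) / 2.0
    signs = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=np.float64
    )
    v = signs * e + np.asarray(center, dtype=np.float64)
    # outward-oriented quads split into triangles (vertex order: -x,+x faces etc.)
    quads = [
        (0, 1, 3, 2),  # -x
        (6, 7, 5, 4),  # +x  (note index math below)
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for a, b_, c, d in quads:
        faces += [(a, b_, c), (a, c, d)]
    return TriangleMesh(v, np.array(faces, dtype=np.int64), name=name)


def _circle(radius, n, z):
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)], axis=1)


def capped_tube(radius: float, length: float, segments: int = 24, rings: int = 8,
                center=(0.0, 0.0, 0.0), name: str = "") -> TriangleMesh:
    """Closed cylinder along +z, centred at ``center``."""
    zs = np.linspace(-length / 2.0, length / 2.0, rings + 1)
    verts = [np.array([0.0, 0.0, -length / 2.0])]
    for z in zs:
        verts.append(_circle(radius, segments, z))
    verts.append(np.array([0.0, 0.0, length / 2.0]))
    v = np.vstack([verts[0][None, :]] + verts[1:-1] + [verts[-1][None, :]])
    faces = []
    bot = 0
    top = len(v) - 1

    def ring_start(r):
        return 1 + r * segments

    for i in range(segments):
        j = (i + 1) % segments
        faces.append((bot, ring_start(0) + j, ring_start(0) + i))
        faces.append((top, ring_start(rings) + i, ring_start(rings) + j))
    for r in range(rings):
        lo, hi = ring_start(r), ring_start(r + 1)
        for i in range(segments):
            j = (i + 1) % segments
            faces.append((lo + i, lo + j, hi + j))
            faces.append((lo + i, hi + j, hi + i))
    mesh_v = v + np.asarray(center, dtype=np.float64)
    return TriangleMesh(mesh_v, np.array(faces, dtype=np.int64), name=name)


def capsule(p0, p1, radius: float, segments: int = 16, cap_rings: int = 6, name: str = "") -> TriangleMesh:
    """Capsule (cylinder with hemispherical caps) from ``p0`` to ``p1``."""
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        return icosphere(radius, 2, center=p0, name=name)
    z = axis / length
    # build in local frame (+z along axis), then rotate
    tmp = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(tmp, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    verts = [np.array([0.0, 0.0, -radius])]
    # ring radii/heights: lower cap z in [-r, 0], upper cap z in [L, L + r]
    ring_specs = []
    for k in range(1, cap_rings + 1):
        ang = -np.pi / 2 + (np.pi / 2) * k / cap_rings
        ring_specs.append((radius * np.cos(ang), radius * np.sin(ang)))
    for k in range(0, cap_rings + 1):
        ang = (np.pi / 2) * k / cap_rings
        ring_specs.append((radius * np.cos(ang), length + radius * np.sin(ang)))
    for rr, zz in ring_specs[:-1]:
        verts.append(_circle(rr, segments, zz))
    verts.append(np.array([0.0, 0.0, length + radius]))
    v_local = np.vstack([verts[0][None, :]] + verts[1:-1] + [verts[-1][None, :]])
    n_rings = len(ring_specs) - 1
    faces = []
    bot, top = 0, len(v_local) - 1

    def ring_start(r):
        return 1 + r * segments

    for i in range(segments):
        j = (i + 1) % segments
        faces.append((bot, ring_start(0) + j, ring_start(0) + i))
        faces.append((top, ring_start(n_rings - 1) + i, ring_start(n_rings - 1) + j))
    for r in range(n_rings - 1):
        lo, hi = ring_start(r), ring_start(r + 1)
        for i in range(segments):
            j = (i + 1) % segments
            faces.append((lo + i, lo + j, hi + j))
            faces.append((lo + i, hi + j, hi + i))
    rot = np.stack([x, y, z], axis=1)
    v_world = v_local @ rot.T + p0
    return TriangleMesh(v_world, np.array(faces, dtype=np.int64), name=name)
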