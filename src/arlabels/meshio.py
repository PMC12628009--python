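"""Triangle-mesh file I/O: PLY (ASCII and binary little-endian) and STL (read-only)."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import ManifestError
from .geometry import TriangleMesh

__all__ = ["load_mesh", "save_ply"]


def save_ply(mesh: TriangleMesh, path, binary: bool = False) -> None:
    """Write a PLY file. ASCII output uses 9-significant-digit floats so the
    byte layout is deterministic for identical input."""
    path = Path(path)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"comment {mesh.name}\n"
        f"element vertex {len(mesh.vertices)}\n"
        "property float x\nproperty float y\nproperty float z\n"
        f"element face {len(mesh.faces)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(mesh.vertices.astype("<f4").tobytes())
            counts = np.full((len(mesh.faces), 1), 3, dtype=np.uint8)
            for cnt, face in zip(counts, mesh.faces.astype("<i4")):
                fh.write(cnt.tobytes() + face.tobytes())
        else:
            lines = []
            for v in mesh.vertices:
                lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            for f in mesh.faces:
                lines.append(f"3 {f[0]} {f[1]} {f[2]}")
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def load_mesh(path, name: str | None = None) -> TriangleMesh:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        v, f = _read_ply(path)
    elif suffix == ".stl":
        v, f = _read_stl(path)
    else:
        raise ManifestError(f"unsupported mesh format: {path}")
    return TriangleMesh(v, f, name=name if name is not None else path.stem)


_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ManifestError(f"{path}: not a PLY file")
        fmt = None
        elements = []  # (name, count, [(prop_name, dtype) | ('list', count_t, item_t, name)])
        while True:
            line = fh.readline()
            if not line:
                raise ManifestError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").strip().split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
                else:
                    elements[-1][2].append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ManifestError(f"{path}: unsupported PLY format {fmt!r}")
        vertices, faces = None, None
        if fmt == "ascii":
            text = fh.read().decode("ascii").split()
            pos = 0
            for ename, count, props in elements:
                rows = []
                for _ in range(count):
                    row = []
                    for prop in props:
                        if prop[0] == "list":
                            n = int(text[pos]); pos += 1
                            row.append([float(text[pos + i]) for i in range(n)])
                            pos += n
                        else:
                            row.append(float(text[pos])); pos += 1
                    rows.append(row)
                if ename == "vertex":
                    names = [p[0] for p in props]
                    ix, iy, iz = names.index("x"), names.index("y"), names.index("z")
                    vertices = np.array([[r[ix], r[iy], r[iz]] for r in rows])
                elif ename == "face":
                    faces = np.array([r[0] for r in rows], dtype=np.int64)
        else:
            for ename, count, props in elements:
                if ename == "vertex" and all(p[0] != "list" for p in props):
                    dtype = np.dtype([(p[0], "<" + _PLY_TYPES[p[1]]) for p in props])
                    data = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype)
                    vertices = np.stack(
                        [data["x"], data["y"], data["z"]], axis=1
                    ).astype(np.float64)
                elif ename == "face":
                    rows = []
                    for _ in range(count):
                        face_row = []
                        for prop in props:
                            if prop[0] == "list":
                                cnt_t = np.dtype("<" + _PLY_TYPES[prop[1]])
                                item_t = np.dtype("<" + _PLY_TYPES[prop[2]])
                                (n,) = np.frombuffer(fh.read(cnt_t.itemsize), dtype=cnt_t)
                                vals = np.frombuffer(fh.read(item_t.itemsize * int(n)), dtype=item_t)
                                face_row = vals.tolist()
                            else:
                                fh.read(np.dtype("<" + _PLY_TYPES[prop[1]]).itemsize)
                        rows.append(face_row)
                    faces = np.array(rows, dtype=np.int64)
                else:  # skip unknown fixed-size element
                    dtype = np.dtype([(p[0], "<" + _PLY_TYPES[p[1]]) for p in props])
                    fh.read(dtype.itemsize * count)
        if vertices is None or faces is None:
            raise ManifestError(f"{path}: PLY missing vertex or face element")
        return vertices, faces


def _read_stl(path: Path):
    raw = path.read_bytes()
    if raw[:5].lower() == b"solid" and b"facet" in raw[:500]:
        return _read_stl_ascii(raw.decode("ascii", "replace"))
    (n_tri,) = struct.unpack("<I", raw[80:84])
    rec = np.dtype(
        [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
    )
    data = np.frombuffer(raw[84 : 84 + rec.itemsize * n_tri], dtype=rec)
    tri = data["v"].astype(np.float64).reshape(-1, 3)
    return _dedupe_vertices(tri)


def _read_stl_ascii(text: str):
    coords = []
    for line in text.splitlines():
        tokens = line.split()
        if tokens and tokens[0] == "vertex":
            coords.append([float(x) for x in tokens[1:4]])
    tri = np.array(coords)
    return _dedupe_vertices(tri)


def _dedupe_vertices(tri: np.ndarray):
    """Merge exactly identical vertices of a triangle soup into an indexed mesh."""
    uniq, inverse = np.unique(tri, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return uniq, faces
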