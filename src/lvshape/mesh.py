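"""Triangle-mesh container, file I/O and preprocessing primitives.

All geometry is in millimetres.  Meshes are plain vertex/face arrays
(``float64`` / ``int64``); LV endocardial surfaces are *open* at the base
after clipping, so no watertightness is assumed anywhere.

Supported file formats: STL (ASCII and binary), PLY (ASCII) and OBJ.
These are written/parsed directly -- the formats are line- or
record-oriented and need no external dependency.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriangleMesh",
    "ClipPlane",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "clip_with_plane",
    "align_barycentre",
    "surface_area",
    "base_plane_from_mitral_points",
    "read_clip_plane_json",
]

_MIN_FACE_AREA = 1e-9  # mm^2; faces below this are degenerate


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed."""


@dataclass
class TriangleMesh:
    """A triangulated surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    label : subject / shape identifier carried through the pipeline
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.label)

    # -- derived quantities ------------------------------------------------

    def face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_normals_area(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit normals and areas per face (area-weighted normal halved cross)."""
        a, b, c = self.face_corners()
        n = 0.5 * np.cross(b - a, c - a)
        area = np.linalg.norm(n, axis=1)
        unit = np.divide(n, area[:, None], out=np.zeros_like(n), where=area[:, None] > 0)
        return unit, area

    def face_centers(self) -> np.ndarray:
        a, b, c = self.face_corners()
        return (a + b + c) / 3.0

    def barycentre(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (i, j) pairs."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def drop_degenerate_faces(self) -> "TriangleMesh":
        """Remove faces with repeated vertices or area below 1e-9 mm^2."""
        f = self.faces
        distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        _, area = self.face_normals_area()
        keep = distinct & (area > _MIN_FACE_AREA)
        return TriangleMesh(self.vertices, f[keep], self.label)

    def validate(self) -> None:
        if self.n_faces == 0:
            raise ValueError("mesh has no faces")
        _, area = self.face_normals_area()
        if (area <= _MIN_FACE_AREA).any():
            raise ValueError("mesh contains degenerate faces")


@dataclass
class ClipPlane:
    """Oriented plane; ``normal`` points toward the half-space that is kept."""

    point: np.ndarray
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if norm == 0:
            raise ValueError("clip plane normal must be non-zero")
        self.normal = self.normal / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.point) @ self.normal


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> TriangleMesh:
    """Read an STL / PLY / OBJ surface mesh (units taken as mm, as stored).

    Binary and ASCII STL are auto-detected.  Non-triangular PLY/OBJ faces
    are fan-triangulated.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    if path.stat().st_size == 0:
        raise MeshFormatError(f"empty mesh file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".stl":
        mesh = _read_stl(path)
    elif suffix == ".ply":
        mesh = _read_ply(path)
    elif suffix == ".obj":
        mesh = _read_obj(path)
    else:
        raise MeshFormatError(f"unsupported mesh format '{suffix}': {path}")
    mesh.label = path.stem
    if mesh.n_faces == 0:
        raise MeshFormatError(f"mesh file contains no faces: {path}")
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path, binary_stl: bool = False) -> None:
    """Write a mesh; format inferred from the file extension."""
    path = Path(path)
    if mesh.n_faces == 0:
        raise ValueError("refusing to write a mesh with zero faces")
    suffix = path.suffix.lower()
    if suffix == ".stl":
        _write_stl(mesh, path, binary=binary_stl)
    elif suffix == ".ply":
        _write_ply(mesh, path)
    elif suffix == ".obj":
        _write_obj(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format '{suffix}': {path}")


def _read_stl(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    # ASCII STL starts with "solid" AND contains "facet"; binary files may
    # also start with "solid", so check for the keyword.
    head = raw[:512].lstrip()
    if head.startswith(b"solid") and b"facet" in raw[:2048]:
        return _read_stl_ascii(raw.decode("ascii", errors="replace"), path)
    return _read_stl_binary(raw, path)


def _read_stl_ascii(text: str, path: Path) -> TriangleMesh:
    tris: list[list[float]] = []
    for line in text.splitlines():
        parts = line.split()
        if parts[:1] == ["vertex"]:
            if len(parts) != 4:
                raise MeshFormatError(f"malformed STL vertex line in {path}")
            tris.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if not tris or len(tris) % 3:
        raise MeshFormatError(f"ASCII STL has no complete facets: {path}")
    return _mesh_from_triangle_soup(np.asarray(tris).reshape(-1, 3, 3))


def _read_stl_binary(raw: bytes, path: Path) -> TriangleMesh:
    if len(raw) < 84:
        raise MeshFormatError(f"binary STL truncated: {path}")
    (n_tri,) = struct.unpack_from("<I", raw, 80)
    expect = 84 + 50 * n_tri
    if len(raw) < expect:
        raise MeshFormatError(f"binary STL truncated ({len(raw)} < {expect} bytes): {path}")
    rec = np.frombuffer(raw, dtype=np.uint8, count=50 * n_tri, offset=84).reshape(n_tri, 50)
    coords = rec[:, 12:48].copy().view("<f4").astype(np.float64).reshape(n_tri, 3, 3)
    return _mesh_from_triangle_soup(coords)


def _mesh_from_triangle_soup(tris: np.ndarray) -> TriangleMesh:
    """Merge exactly-equal corner coordinates into shared vertices."""
    flat = tris.reshape(-1, 3)
    verts, inverse = np.unique(flat.round(decimals=8), axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(verts, faces).drop_degenerate_faces()


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    normals, _ = mesh.face_normals_area()
    a, b, c = mesh.face_corners()
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", mesh.n_faces))
            rec = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
            data = np.concatenate([normals, a, b, c], axis=1).astype("<f4")
            rec[:, :48] = data.view(np.uint8).reshape(mesh.n_faces, 48)
            fh.write(rec.tobytes())
    else:
        lines = [f"solid {mesh.label or 'mesh'}"]
        for ni, ai, bi, ci in zip(normals, a, b, c):
            lines.append(f" facet normal {ni[0]:.9e} {ni[1]:.9e} {ni[2]:.9e}")
            lines.append("  outer loop")
            for v in (ai, bi, ci):
                lines.append(f"   vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("  endloop")
            lines.append(" endfacet")
        lines.append(f"endsolid {mesh.label or 'mesh'}")
        path.write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> TriangleMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"not a PLY file: {path}")
    n_vert = n_face = 0
    i = 1
    fmt = None
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element" and parts[1] == "vertex":
            n_vert = int(parts[2])
        elif parts[0] == "element" and parts[1] == "face":
            n_face = int(parts[2])
        elif parts[0] == "end_header":
            break
    if fmt != "ascii":
        raise MeshFormatError(f"only ASCII PLY is supported: {path}")
    body = [ln.split() for ln in lines[i:] if ln.strip()]
    if len(body) < n_vert + n_face:
        raise MeshFormatError(f"PLY body truncated: {path}")
    verts = np.array([[float(x) for x in row[:3]] for row in body[:n_vert]])
    faces: list[list[int]] = []
    for row in body[n_vert : n_vert + n_face]:
        k = int(row[0])
        poly = [int(x) for x in row[1 : 1 + k]]
        for j in range(1, k - 1):  # fan triangulation
            faces.append([poly[0], poly[j], poly[j + 1]])
    return TriangleMesh(verts, np.asarray(faces)).drop_degenerate_faces()


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    out = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    out += [f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}" for v in mesh.vertices]
    out += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    path.write_text("\n".join(out) + "\n")


def _read_obj(path: Path) -> TriangleMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            for j in range(1, len(idx) - 1):
                faces.append([idx[0], idx[j], idx[j + 1]])
    if not verts:
        raise MeshFormatError(f"OBJ file has no vertices: {path}")
    return TriangleMesh(np.asarray(verts), np.asarray(faces)).drop_degenerate_faces()


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    out = [f"v {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}" for v in mesh.vertices]
    out += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm^2 (sum of triangle areas)."""
    _, area = mesh.face_normals_area()
    return float(area.sum())


def align_barycentre(meshes: list[TriangleMesh]) -> list[TriangleMesh]:
    """Translate each mesh so its vertex barycentre sits at the origin.

    Translation only -- no rotation or scaling is applied, so pairwise
    vertex distances are preserved exactly.
    """
    if not meshes:
        raise ValueError("align_barycentre: empty mesh list")
    out = []
    for m in meshes:
        out.append(TriangleMesh(m.vertices - m.barycentre(), m.faces.copy(), m.label))
    return out


def clip_with_plane(mesh: TriangleMesh, plane: ClipPlane, tol: float = 1e-6) -> TriangleMesh:
    """Keep the half-space ``(v - point) . normal >= 0``; split crossing triangles.

    Triangles straddling the plane are cut exactly at the plane, producing
    one or two new triangles on the kept side.  The result is open along
    the cut (no cap), which is the desired state for an LV surface clipped
    at the base.
    """
    d = plane.signed_distance(mesh.vertices)
    if (d < tol).all():
        raise ValueError("empty clip result: plane keeps no part of the mesh")
    if (d >= -tol).all():
        return mesh.copy()

    verts: list[np.ndarray] = [mesh.vertices]
    new_pts: list[np.ndarray] = []
    faces_out: list[tuple[int, int, int]] = []
    n0 = mesh.n_vertices
    edge_cut: dict[tuple[int, int], int] = {}

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key in edge_cut:
            return edge_cut[key]
        t = d[i] / (d[i] - d[j])
        p = mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i])
        new_pts.append(p)
        idx = n0 + len(new_pts) - 1
        edge_cut[key] = idx
        return idx

    for tri in mesh.faces:
        inside = d[tri] >= 0.0
        k = int(inside.sum())
        if k == 3:
            faces_out.append(tuple(tri))
        elif k == 0:
            continue
        elif k == 1:
            # one kept vertex a; replace the two lost corners by cut points
            order = np.argsort(~inside)  # kept vertex first
            a, b, c = tri[order]
            # preserve orientation: find cyclic rotation with kept first
            rot = [i for i in range(3) if inside[i]][0]
            a, b, c = tri[rot], tri[(rot + 1) % 3], tri[(rot + 2) % 3]
            faces_out.append((a, cut_point(a, b), cut_point(a, c)))
        else:  # k == 2, one lost vertex
            rot = [i for i in range(3) if not inside[i]][0]
            a, b, c = tri[rot], tri[(rot + 1) % 3], tri[(rot + 2) % 3]
            pab, pca = cut_point(a, b), cut_point(c, a)
            faces_out.append((pab, b, c))
            faces_out.append((pab, c, pca))

    if new_pts:
        verts.append(np.asarray(new_pts))
    all_verts = np.concatenate(verts, axis=0)
    out = TriangleMesh(all_verts, np.asarray(faces_out), mesh.label)
    out = _compact_vertices(out)
    return out.drop_degenerate_faces()


def _compact_vertices(mesh: TriangleMesh) -> TriangleMesh:
    """Drop vertices not referenced by any face; reindex faces."""
    used = np.unique(mesh.faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[mesh.faces], mesh.label)


def connected_component_count(mesh: TriangleMesh) -> int:
    """Number of edge-connected face components (reported after clipping)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if mesh.n_faces == 0:
        return 0
    # faces sharing a vertex are connected
    f = mesh.faces
    rows = np.repeat(np.arange(mesh.n_faces), 3)
    cols = f.ravel()
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(mesh.n_faces, mesh.n_vertices))
    g = adj @ adj.T
    n, _ = connected_components(g, directed=False)
    return int(n)


def base_plane_from_mitral_points(p1, p2, p3, interior_point) -> ClipPlane:
    """Clip plane through three mitral-annulus landmarks.

    The normal is oriented toward ``interior_point`` (an apex-side point),
    so clipping keeps the ventricle and discards the atrium.
    """
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(n) < 1e-12:
        raise ValueError("mitral points are collinear; cannot define a base plane")
    n = n / np.linalg.norm(n)
    if (np.asarray(interior_point) - p1) @ n < 0:
        n = -n
    return ClipPlane(point=p1, normal=n)


def read_clip_plane_json(path: str | Path) -> ClipPlane:
    """Read a ``{"point": [x,y,z], "normal": [x,y,z]}`` sidecar."""
    data = json.loads(Path(path).read_text())
    return ClipPlane(point=np.asarray(data["point"]), normal=np.asarray(data["normal"]))
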