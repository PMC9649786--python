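"""Uniform isotropic remeshing to a target edge length.

The classic incremental scheme: repeatedly split edges longer than 4/3 of
the target, collapse edges shorter than 4/5 of the target, flip edges
toward regular vertex valence, then relax vertices tangentially and
project them back onto the original surface so the geometry (and hence
surface area) is preserved.  Boundary loops (the open LV base) are kept:
boundary vertices may slide along splits but are never smoothed off the
rim and boundary edges are never flipped.
"""

from __future__ import annotations

import numpy as np

from .mesh import TriangleMesh

__all__ = ["remesh_isotropic", "closest_point_on_surface", "mean_edge_length"]


def mean_edge_length(mesh: TriangleMesh) -> float:
    e = mesh.edges()
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return float(d.mean())


def closest_point_on_surface(points: np.ndarray, mesh: TriangleMesh,
                             chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on a triangle mesh and their distances.

    A centroid-distance prefilter (centroid distance minus face
    circumradius lower-bounds the true distance) narrows each query to a
    few candidate faces before the exact point-triangle projection
    (Ericson's region test) is applied.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    a, b, c = mesh.face_corners()
    cent = (a + b + c) / 3.0
    circum = np.maximum(
        np.maximum(
            np.linalg.norm(a - cent, axis=1), np.linalg.norm(b - cent, axis=1)
        ),
        np.linalg.norm(c - cent, axis=1),
    )
    out_pts = np.empty_like(points)
    out_d = np.empty(len(points))
    for s0 in range(0, len(points), chunk):
        p = points[s0 : s0 + chunk]
        d_cent = np.sqrt(
            np.maximum(
                ((p[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2), 0.0
            )
        )
        lower = d_cent - circum[None, :]
        upper = (d_cent + circum[None, :]).min(axis=1)
        for i in range(len(p)):
            cand = np.nonzero(lower[i] <= upper[i] + 1e-12)[0]
            cp, cd = _closest_on_faces(p[i], a[cand], b[cand], c[cand])
            j = int(np.argmin(cd))
            out_pts[s0 + i] = cp[j]
            out_d[s0 + i] = cd[j]
    return out_pts, out_d


def _closest_on_faces(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Exact closest point from ``p`` to each triangle (vectorised)."""
    ab, ac = b - a, c - a
    ap = p[None, :] - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p[None, :] - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp_ = p[None, :] - c
    d5 = (ab * cp_).sum(1)
    d6 = (ac * cp_).sum(1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.clip(np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0), 0, 1)

    cand = a + v[:, None] * ab + w[:, None] * ac
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    reg_ab = (~reg_a) & (~reg_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    reg_ac = (~reg_a) & (~reg_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    reg_bc = (~reg_b) & (~reg_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    cand = np.where(reg_bc[:, None], b + t_bc[:, None] * (c - b), cand)
    cand = np.where(reg_ac[:, None], a + t_ac[:, None] * ac, cand)
    cand = np.where(reg_ab[:, None], a + t_ab[:, None] * ab, cand)
    cand = np.where(reg_c[:, None], c, cand)
    cand = np.where(reg_b[:, None], b, cand)
    cand = np.where(reg_a[:, None], a, cand)
    dist = np.linalg.norm(cand - p[None, :], axis=1)
    return cand, dist


class _EditableMesh:
    """Half-edge-free editable mesh: python dicts over small meshes."""

    def __init__(self, mesh: TriangleMesh):
        self.v: list[np.ndarray] = [np.array(p) for p in mesh.vertices]
        self.faces: dict[int, tuple[int, int, int]] = dict(enumerate(map(tuple, mesh.faces)))
        self.next_face = len(self.faces)
        self._rebuild()

    def _rebuild(self) -> None:
        self.edge_faces: dict[tuple[int, int], list[int]] = {}
        self.vert_faces: dict[int, set[int]] = {}
        for fid, tri in self.faces.items():
            for i in range(3):
                e = _key(tri[i], tri[(i + 1) % 3])
                self.edge_faces.setdefault(e, []).append(fid)
            for vi in tri:
                self.vert_faces.setdefault(vi, set()).add(fid)

    # -- queries ----------------------------------------------------------

    def is_boundary_edge(self, e: tuple[int, int]) -> bool:
        return len(self.edge_faces.get(e, [])) == 1

    def boundary_vertices(self) -> set[int]:
        out: set[int] = set()
        for e, fl in self.edge_faces.items():
            if len(fl) == 1:
                out.update(e)
        return out

    def vertex_neighbors(self, vi: int) -> set[int]:
        nb: set[int] = set()
        for fid in self.vert_faces.get(vi, ()):  # pragma: no branch
            nb.update(self.faces[fid])
        nb.discard(vi)
        return nb

    def valence(self, vi: int) -> int:
        return len(self.vertex_neighbors(vi))

    # -- edits (each followed by local bookkeeping) -----------------------

    def _remove_face(self, fid: int) -> None:
        tri = self.faces.pop(fid)
        for i in range(3):
            e = _key(tri[i], tri[(i + 1) % 3])
            lst = self.edge_faces.get(e)
            if lst and fid in lst:
                lst.remove(fid)
                if not lst:
                    del self.edge_faces[e]
        for vi in tri:
            self.vert_faces[vi].discard(fid)

    def _add_face(self, tri: tuple[int, int, int]) -> int:
        fid = self.next_face
        self.next_face += 1
        self.faces[fid] = tri
        for i in range(3):
            e = _key(tri[i], tri[(i + 1) % 3])
            self.edge_faces.setdefault(e, []).append(fid)
        for vi in tri:
            self.vert_faces.setdefault(vi, set()).add(fid)
        return fid

    def split_edge(self, e: tuple[int, int]) -> None:
        i, j = e
        mid = 0.5 * (self.v[i] + self.v[j])
        self.v.append(mid)
        m = len(self.v) - 1
        for fid in list(self.edge_faces.get(e, [])):
            tri = self.faces[fid]
            k = [x for x in tri if x not in e][0]
            # preserve winding
            idx = tri.index(i)
            if tri[(idx + 1) % 3] == j:
                t1, t2 = (i, m, k), (m, j, k)
            else:
                t1, t2 = (m, i, k), (j, m, k)
            self._remove_face(fid)
            self._add_face(t1)
            self._add_face(t2)

    def can_collapse(self, e: tuple[int, int], boundary: set[int]) -> bool:
        i, j = e
        if (i in boundary) != (j in boundary):
            return False
        if self.is_boundary_edge(e) and not (i in boundary and j in boundary):
            return False
        # link condition: common neighbors must be exactly the face apexes
        apexes = set()
        for fid in self.edge_faces.get(e, []):
            apexes.update(x for x in self.faces[fid] if x not in e)
        common = self.vertex_neighbors(i) & self.vertex_neighbors(j)
        return common == apexes

    def collapse_edge(self, e: tuple[int, int]) -> None:
        i, j = e
        self.v[i] = 0.5 * (self.v[i] + self.v[j])
        dead = list(self.edge_faces.get(e, []))
        for fid in dead:
            self._remove_face(fid)
        for fid in list(self.vert_faces.get(j, set())):
            tri = self.faces[fid]
            new = tuple(i if x == j else x for x in tri)
            self._remove_face(fid)
            if len(set(new)) == 3:
                self._add_face(new)
        self.vert_faces.pop(j, None)

    def flip_edge(self, e: tuple[int, int]) -> bool:
        fl = self.edge_faces.get(e, [])
        if len(fl) != 2:
            return False
        i, j = e
        f1, f2 = fl
        k1 = [x for x in self.faces[f1] if x not in e][0]
        k2 = [x for x in self.faces[f2] if x not in e][0]
        if k1 == k2 or _key(k1, k2) in self.edge_faces:
            return False
        tri1 = self.faces[f1]
        idx = tri1.index(i)
        if tri1[(idx + 1) % 3] == j:
            new1, new2 = (i, k2, k1), (j, k1, k2)
        else:
            new1, new2 = (i, k1, k2), (j, k2, k1)
        self._remove_face(f1)
        self._remove_face(f2)
        self._add_face(new1)
        self._add_face(new2)
        return True

    def to_mesh(self, label: str = "") -> TriangleMesh:
        used = sorted({v for tri in self.faces.values() for v in tri})
        remap = {old: new for new, old in enumerate(used)}
        verts = np.asarray([self.v[i] for i in used])
        faces = np.asarray([[remap[x] for x in tri] for tri in self.faces.values()])
        return TriangleMesh(verts, faces, label)


def _key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def remesh_isotropic(
    mesh: TriangleMesh,
    target_edge: float = 4.0,
    n_iter: int = 5,
    project: bool = True,
) -> TriangleMesh:
    """Remesh toward a uniform target edge length (default 4 mm).

    Parameters
    ----------
    mesh : input surface (>= 4 faces)
    target_edge : desired mean edge length in mm
    n_iter : split/collapse/flip/smooth sweeps
    project : project relaxed vertices back onto the input surface
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    if mesh.n_faces < 4:
        raise ValueError("mesh too small to remesh (< 4 faces)")
    diam = np.linalg.norm(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0))
    if target_edge > diam:
        raise ValueError(
            f"target too coarse: edge {target_edge} mm exceeds mesh diameter {diam:.1f} mm"
        )

    em = _EditableMesh(mesh.drop_degenerate_faces())
    high, low = 4.0 / 3.0 * target_edge, 4.0 / 5.0 * target_edge

    for _ in range(n_iter):
        # 1. split long edges
        for e in sorted(em.edge_faces.keys()):
            if e not in em.edge_faces:
                continue
            if np.linalg.norm(em.v[e[0]] - em.v[e[1]]) > high:
                em.split_edge(e)
        # 2. collapse short edges
        boundary = em.boundary_vertices()
        for e in sorted(em.edge_faces.keys()):
            if e not in em.edge_faces:
                continue
            i, j = e
            if j >= len(em.v) or i >= len(em.v):
                continue
            if np.linalg.norm(em.v[i] - em.v[j]) < low and em.can_collapse(e, boundary):
                # avoid creating overlong edges
                mid = 0.5 * (em.v[i] + em.v[j])
                nb = (em.vertex_neighbors(i) | em.vertex_neighbors(j)) - {i, j}
                if all(np.linalg.norm(em.v[n] - mid) <= high for n in nb):
                    em.collapse_edge(e)
        # 3. valence-equalising flips (interior edges only)
        boundary = em.boundary_vertices()
        for e in sorted(em.edge_faces.keys()):
            fl = em.edge_faces.get(e)
            if not fl or len(fl) != 2:
                continue
            i, j = e
            k1 = [x for x in em.faces[fl[0]] if x not in e][0]
            k2 = [x for x in em.faces[fl[1]] if x not in e][0]

            def dev(vi: int, delta: int = 0) -> int:
                tgt = 4 if vi in boundary else 6
                return abs(em.valence(vi) + delta - tgt)

            before = dev(i) + dev(j) + dev(k1) + dev(k2)
            after = dev(i, -1) + dev(j, -1) + dev(k1, +1) + dev(k2, +1)
            if after < before:
                em.flip_edge(e)
        # 4. tangential relaxation + projection
        cur = em.to_mesh()
        em2 = _EditableMesh(cur)
        boundary = em2.boundary_vertices()
        verts = np.asarray(em2.v)
        normals = _vertex_normals(cur)
        new_verts = verts.copy()
        for vi in range(len(verts)):
            if vi in boundary:
                continue
            nb = em2.vertex_neighbors(vi)
            if not nb:
                continue
            g = verts[list(nb)].mean(axis=0)
            d = g - verts[vi]
            d -= (d @ normals[vi]) * normals[vi]  # tangential component only
            new_verts[vi] = verts[vi] + 0.6 * d
        if project:
            proj, _ = closest_point_on_surface(new_verts, mesh)
            interior = np.ones(len(new_verts), dtype=bool)
            interior[list(boundary)] = False
            new_verts[interior] = proj[interior]
        for vi in range(len(new_verts)):
            em2.v[vi] = new_verts[vi]
        em = em2

    out = em.to_mesh(mesh.label).drop_degenerate_faces()
    out.validate()
    return out


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    fn, area = mesh.face_normals_area()
    vn = np.zeros_like(mesh.vertices)
    w = fn * area[:, None]
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], w)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    return np.divide(vn, norms, out=np.zeros_like(vn), where=norms > 0)
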