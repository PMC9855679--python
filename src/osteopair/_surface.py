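"""Exact closest-point queries against a triangulated surface.

The query is KD-tree accelerated but exact: candidate triangles come from a
tree over face centroids, and a point's result is only accepted when the
k-th candidate centroid is provably too far to hide a closer triangle
(bound: any triangle within surface distance d has its centroid within
d + r_max, r_max being the largest centroid-to-vertex distance).  Points
failing the bound fall back to testing every triangle.

Ties at exactly equal distance resolve to the lowest face index: candidates
are scanned in ascending face order and ``argmin`` keeps the first minimum.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import TriangleMesh


def closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                            c: np.ndarray):
    """Closest point on triangle (a, b, c) to p, elementwise over matched
    (n, 3) arrays.  Returns (points, barycentric) each (n, 3).

    Region classification after Ericson's *Real-Time Collision Detection*
    treatment, fully vectorised.
    """
    p = np.atleast_2d(p)
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    # branch parameters; division is safe inside each selected branch for
    # non-degenerate triangles (zero denominators only occur in regions the
    # branch conditions exclude)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        s = va + vb + vc
        v_in = vb / s
        w_in = vc / s

    conds = [(d1 <= 0) & (d2 <= 0),                   # region: vertex a
             (d3 >= 0) & (d4 <= d3),                  # vertex b
             (d6 >= 0) & (d5 <= d6),                  # vertex c
             (vc <= 0) & (d1 >= 0) & (d3 <= 0),       # edge ab
             (vb <= 0) & (d2 >= 0) & (d6 <= 0),       # edge ac
             (va <= 0) & (d4 >= d3) & (d5 >= d6)]     # edge bc
    bv = np.select(conds, [0.0, 1.0, 0.0, v_ab, 0.0, 1 - w_bc], default=v_in)
    bw = np.select(conds, [0.0, 0.0, 1.0, 0.0, w_ac, w_bc], default=w_in)
    points = a + bv[:, None] * ab + bw[:, None] * ac
    bary = np.column_stack([1.0 - bv - bw, bv, bw])
    return points, bary


try:               # compiled kernel; the numpy staged path is the fallback
    from numba import njit
except ImportError:                                     # pragma: no cover
    njit = None

if njit is not None:
    @njit(cache=True)
    def _closest_brute_nb(points, tri):   # pragma: no cover - compiled
        n = points.shape[0]
        nf = tri.shape[0]
        dist = np.empty(n)
        cp = np.empty((n, 3))
        face = np.empty(n, dtype=np.int64)
        bary = np.empty((n, 3))
        for i in range(n):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            best = np.inf
            bj = -1
            bu = bv = bw = 0.0
            bqx = bqy = bqz = 0.0
            for j in range(nf):
                ax, ay, az = tri[j, 0, 0], tri[j, 0, 1], tri[j, 0, 2]
                bx, by, bz = tri[j, 1, 0], tri[j, 1, 1], tri[j, 1, 2]
                cx, cy, cz = tri[j, 2, 0], tri[j, 2, 1], tri[j, 2, 2]
                abx = bx - ax; aby = by - ay; abz = bz - az
                acx = cx - ax; acy = cy - ay; acz = cz - az
                apx = px - ax; apy = py - ay; apz = pz - az
                d1 = abx * apx + aby * apy + abz * apz
                d2 = acx * apx + acy * apy + acz * apz
                if d1 <= 0.0 and d2 <= 0.0:
                    u = 1.0; v = 0.0; w = 0.0
                    qx, qy, qz = ax, ay, az
                else:
                    bpx = px - bx; bpy = py - by; bpz = pz - bz
                    d3 = abx * bpx + aby * bpy + abz * bpz
                    d4 = acx * bpx + acy * bpy + acz * bpz
                    if d3 >= 0.0 and d4 <= d3:
                        u = 0.0; v = 1.0; w = 0.0
                        qx, qy, qz = bx, by, bz
                    else:
                        cpx = px - cx; cpy = py - cy; cpz = pz - cz
                        d5 = abx * cpx + aby * cpy + abz * cpz
                        d6 = acx * cpx + acy * cpy + acz * cpz
                        if d6 >= 0.0 and d5 <= d6:
                            u = 0.0; v = 0.0; w = 1.0
                            qx, qy, qz = cx, cy, cz
                        else:
                            vc = d1 * d4 - d3 * d2
                            vb = d5 * d2 - d1 * d6
                            va = d3 * d6 - d5 * d4
                            if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                                t = d1 / (d1 - d3)
                                u = 1.0 - t; v = t; w = 0.0
                                qx = ax + t * abx; qy = ay + t * aby; qz = az + t * abz
                            elif vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                t = d2 / (d2 - d6)
                                u = 1.0 - t; v = 0.0; w = t
                                qx = ax + t * acx; qy = ay + t * acy; qz = az + t * acz
                            elif va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
                                t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                u = 0.0; v = 1.0 - t; w = t
                                qx = bx + t * (cx - bx)
                                qy = by + t * (cy - by)
                                qz = bz + t * (cz - bz)
                            else:
                                denom = 1.0 / (va + vb + vc)
                                v = vb * denom; w = vc * denom; u = 1.0 - v - w
                                qx = ax + abx * v + acx * w
                                qy = ay + aby * v + acy * w
                                qz = az + abz * v + acz * w
                dx = px - qx; dy = py - qy; dz = pz - qz
                dsq = dx * dx + dy * dy + dz * dz
                if dsq < best:        # strict: exact ties keep the lowest face
                    best = dsq
                    bj = j
                    bu, bv, bw = u, v, w
                    bqx, bqy, bqz = qx, qy, qz
            dist[i] = np.sqrt(best)
            face[i] = bj
            bary[i, 0] = bu; bary[i, 1] = bv; bary[i, 2] = bw
            cp[i, 0] = bqx; cp[i, 1] = bqy; cp[i, 2] = bqz
        return dist, cp, face, bary


class ClosestResult(NamedTuple):
    distance: np.ndarray   #: unsigned distance per query point, mm
    point: np.ndarray      #: (n, 3) closest point on the surface
    face: np.ndarray       #: face index of the closest triangle
    bary: np.ndarray       #: (n, 3) barycentric coordinates on that face


class SurfaceQuery:
    """Reusable closest-point structure over one fixed mesh."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self.tri = mesh.vertices[mesh.faces]           # (f, 3, 3)
        self._tri_c = np.ascontiguousarray(self.tri)
        self.centroids = self.tri.mean(axis=1)
        self._ctree = cKDTree(self.centroids)
        self._vtree = cKDTree(mesh.vertices)
        self.r_max = float(np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max())
        self._vertex_normals = None

    @property
    def vertex_normals(self) -> np.ndarray:
        if self._vertex_normals is None:
            self._vertex_normals = self.mesh.vertex_normals()
        return self._vertex_normals

    def _exact_over(self, points, cand):
        """Exact closest over candidate faces ``cand`` (n, k), returns
        (distance, point, face, bary)."""
        n, k = cand.shape
        idx = np.repeat(np.arange(n), k)
        f = cand.ravel()
        cp, bary = closest_point_triangles(points[idx],
                                           self.tri[f, 0], self.tri[f, 1],
                                           self.tri[f, 2])
        d2 = ((points[idx] - cp) ** 2).sum(1).reshape(n, k)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        flat = rows * k + best
        return (np.sqrt(d2[rows, best]), cp[flat], f[flat], bary[flat])

    def closest(self, points: np.ndarray, k: int = 16) -> ClosestResult:
        """Closest point on the surface for each query point (exact)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        nf = len(self.tri)
        if njit is not None and nf <= 20000:
            return ClosestResult(*_closest_brute_nb(
                np.ascontiguousarray(points), self._tri_c))
        if nf <= max(k, 16):
            cand = np.broadcast_to(np.arange(nf), (len(points), nf))
            res = self._exact_over(points, cand)
            return ClosestResult(*res)
        n = len(points)
        dist = np.empty(n)
        cp = np.empty((n, 3))
        face = np.empty(n, dtype=np.int64)
        bary = np.empty((n, 3))
        todo = np.arange(n)
        # escalate k until the k-th candidate centroid certifies the result:
        # a missed triangle would need its centroid within dist + r_max
        for kk in (min(k, nf), nf):
            pts = points[todo]
            if kk < nf:
                dc, cand = self._ctree.query(pts, k=kk)
                cand = np.sort(cand, axis=1)    # ascending face order for ties
                d, c, f, b = self._exact_over(pts, cand)
                certified = d <= dc[:, -1] - self.r_max
            else:
                cand = np.broadcast_to(np.arange(nf), (len(pts), nf))
                d, c, f, b = self._exact_over(pts, cand)
                certified = np.ones(len(pts), dtype=bool)
            ok = todo[certified]
            dist[ok] = d[certified]
            cp[ok] = c[certified]
            face[ok] = f[certified]
            bary[ok] = b[certified]
            todo = todo[~certified]
            if len(todo) == 0:
                break
        return ClosestResult(dist, cp, face, bary)

    def closest_vertices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-vertex query (distance, vertex index) — the coarser
        correspondence mode."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d, idx = self._vtree.query(points)
        return d, idx

    def interpolated_normals(self, face: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of vertex normals at surface points."""
        vn = self.vertex_normals[self.mesh.faces[face]]        # (n, 3, 3)
        n = np.einsum("nk,nkj->nj", bary, vn)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm
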