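"""Geometric preprocessing: mirroring and visibility hollowing.

Mirroring converts a left element to right chirality so it can be
superimposed on a right element; the reflection plane is immaterial because
the subsequent rigid registration absorbs any rigid difference.

Hollowing emulates the "select by visibility" cleanup applied to segmented
bone models: faces that no external viewpoint can see (remnant trabecular
geometry inside the cortical shell) are deleted, leaving the outer shell
that registration should operate on.
"""

from __future__ import annotations

import numpy as np

from .errors import ProcessingError, ValidationError
from .mesh_io import LandmarkSet, Side, TriangleMesh, validate_mesh

_PLANES = {"x": 0, "y": 1, "z": 2}


def _plane_axis(plane: str) -> int:
    key = str(plane).lower().rstrip("=0")
    if key not in _PLANES:
        raise ValidationError(f"unknown mirror plane {plane!r}; use x, y or z")
    return _PLANES[key]


def mirror_mesh(mesh: TriangleMesh, plane: str = "x") -> TriangleMesh:
    """Reflect a mesh across a coordinate plane, preserving outward
    orientation by reversing face winding, and flip its side flag.

    An involution: ``mirror(mirror(m))`` equals ``m`` vertex-wise.
    """
    axis = _plane_axis(plane)
    v = mesh.vertices.copy()
    v[:, axis] = -v[:, axis]
    f = mesh.faces[:, ::-1].copy()
    side = {Side.LEFT: Side.RIGHT, Side.RIGHT: Side.LEFT,
            Side.UNKNOWN: Side.UNKNOWN}[mesh.side]
    return TriangleMesh(id=mesh.id, vertices=v, faces=f, side=side)


def mirror_landmarks(landmarks: LandmarkSet, plane: str = "x") -> LandmarkSet:
    """Reflect a landmark set with the same plane used for its mesh."""
    axis = _plane_axis(plane)
    pts = {}
    for name, p in landmarks.points.items():
        q = np.array(p, dtype=np.float64)
        q[axis] = -q[axis]
        pts[name] = q
    return LandmarkSet(mesh_id=landmarks.mesh_id, points=pts)


def sphere_directions(n: int) -> np.ndarray:
    """First ``n`` directions of a nested quasi-uniform sequence on the unit
    sphere (Halton bases 2 and 3 mapped by area-preserving projection).

    Nested: the first m < n directions of the sequence are a prefix of the
    first n, which makes hollowing monotone in ``n_directions``.
    """
    def van_der_corput(k, base):
        x, denom = 0.0, 1.0
        while k:
            k, rem = divmod(k, base)
            denom *= base
            x += rem / denom
        return x

    i = np.arange(1, n + 1)
    z = 1.0 - 2.0 * np.array([van_der_corput(k, 2) for k in i])
    phi = 2.0 * np.pi * np.array([van_der_corput(k, 3) for k in i])
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _segment_hits(origin: np.ndarray, targets: np.ndarray, tri: np.ndarray,
                  exclude: np.ndarray) -> np.ndarray:
    """For each target, is the segment origin→target blocked by any triangle
    (Möller–Trumbore, broadcast rays × triangles)?

    ``exclude`` is an (n_targets, n_faces) bool mask of triangles that may
    legitimately contain the target itself (incident faces).
    Returns a bool array: True = target visible from origin.
    """
    dirs = targets - origin                         # (r, 3)
    e1 = tri[:, 1] - tri[:, 0]                      # (f, 3)
    e2 = tri[:, 2] - tri[:, 0]
    tvec = origin[None, :] - tri[:, 0, :]           # (f, 3) — origin is shared
    pvec = np.cross(dirs[:, None, :], e2[None, :, :])   # (r, f, 3)
    det = np.einsum("fj,rfj->rf", e1, pvec)
    near_parallel = np.abs(det) < 1e-12
    det_safe = np.where(near_parallel, 1.0, det)
    u = np.einsum("fj,rfj->rf", tvec, pvec) / det_safe
    qvec = np.cross(tvec, e1)                       # (f, 3)
    v = np.einsum("rj,fj->rf", dirs, qvec) / det_safe
    t = np.einsum("fj,fj->f", e2, qvec)[None, :] / det_safe
    eps = 1e-9
    hit = (~near_parallel & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
           & (t > eps) & (t < 1.0 - 1e-7) & ~exclude)
    return ~hit.any(axis=1)


def hollow_mesh(mesh: TriangleMesh, n_directions: int = 256,
                offset_factor: float = 1.5, mode: str = "face") -> TriangleMesh:
    """Remove interior faces that no external viewpoint can see.

    Viewpoints sit on a sphere of radius ``offset_factor`` times the
    bounding-sphere radius, at :func:`sphere_directions` positions.  A face
    counts as visible when any of its three vertices or its centroid is
    reachable from some viewpoint by an unblocked straight segment
    (conservative retention: partial occlusion does not delete a face).

    ``mode="face"`` keeps exactly the visible faces; ``mode="component"``
    keeps every connected component containing at least one visible face
    (the coarser interpretation of interior-structure deletion).
    """
    if n_directions < 1:
        raise ValidationError("n_directions must be >= 1")
    if offset_factor <= 1.0:
        raise ValidationError("offset_factor must exceed 1 (outside the mesh)")
    if mode not in ("face", "component"):
        raise ValidationError(f"unknown hollow mode {mode!r}")

    v = mesh.vertices
    faces = mesh.faces
    center = 0.5 * (v.min(axis=0) + v.max(axis=0))
    radius = float(np.linalg.norm(v - center, axis=1).max())
    if radius == 0:
        raise ProcessingError("degenerate mesh: zero bounding radius")
    viewpoints = center + offset_factor * radius * sphere_directions(n_directions)

    tri = v[faces]
    centroids = tri.mean(axis=1)
    nv, nf = len(v), len(faces)

    # incidence masks so a target is never occluded by its own triangle(s)
    vert_inc = np.zeros((nv, nf), dtype=bool)
    for k in range(3):
        vert_inc[faces[:, k], np.arange(nf)] = True

    vertex_seen = np.zeros(nv, dtype=bool)
    face_seen = np.zeros(nf, dtype=bool)
    for p in viewpoints:
        todo_v = np.flatnonzero(~vertex_seen)
        if len(todo_v):
            vis = _segment_hits(p, v[todo_v], tri, vert_inc[todo_v])
            vertex_seen[todo_v[vis]] = True
        face_seen |= vertex_seen[faces].any(axis=1)
        todo_f = np.flatnonzero(~face_seen)
        if len(todo_f):
            self_mask = np.zeros((len(todo_f), nf), dtype=bool)
            self_mask[np.arange(len(todo_f)), todo_f] = True
            vis = _segment_hits(p, centroids[todo_f], tri, self_mask)
            face_seen[todo_f[vis]] = True
        if face_seen.all():
            break

    if mode == "component":
        face_seen = _spread_to_components(faces, face_seen)

    if not face_seen.any():
        raise ProcessingError(
            f"mesh '{mesh.id}': no face visible from {n_directions} viewpoints")
    out = TriangleMesh(id=mesh.id, vertices=v, faces=faces[face_seen],
                       side=mesh.side)
    return validate_mesh(out)


def _spread_to_components(faces: np.ndarray, seen: np.ndarray) -> np.ndarray:
    """Mark every face sharing a connected component (via shared vertices)
    with a seen face."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    nf = len(faces)
    # faces are connected if they share any vertex
    nv = faces.max() + 1
    rows = np.repeat(np.arange(nf), 3)
    cols = faces.ravel()
    fv = coo_matrix((np.ones(3 * nf), (rows, cols)), shape=(nf, nv)).tocsr()
    adj = fv @ fv.T
    _, labels = connected_components(adj, directed=False)
    keep_labels = np.unique(labels[seen])
    return np.isin(labels, keep_labels)
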