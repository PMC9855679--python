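"""Triangle-mesh and landmark I/O with geometry validation.

Meshes are bone surface models in millimetres, stored as STL (ASCII or
binary) or ASCII PLY.  Neither format records units; everything in this
package is millimetres.  Landmarks travel in a sidecar JSON file because STL
cannot carry point annotations.

STL duplicates every vertex per facet, so reading merges coincident vertices
(tolerance 1e-9 mm — far below any scanner resolution, so merging restores
connectivity without moving geometry) and drops zero-area facets.
"""

from __future__ import annotations

import json
import logging
import re
import struct
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import MeshFormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

MERGE_TOL_MM = 1e-9
#: the three anatomical landmarks seeding coarse alignment: most superior /
#: most inferior point of the pubic symphysis, most medial point of the
#: obturator foramen
REQUIRED_LANDMARKS = ("sym_sup", "sym_inf", "obt_med")


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated bone surface.

    Parameters
    ----------
    id : str
        Label for the mesh (usually ``"<individual>_<side>"``).
    vertices : (n, 3) float array
        Vertex coordinates in millimetres.
    faces : (m, 3) int array
        Vertex-index triples; consistently wound after :func:`validate_mesh`.
    side : Side
        Anatomical side, flipped by mirroring.
    """

    id: str
    vertices: np.ndarray
    faces: np.ndarray
    side: Side = Side.UNKNOWN

    def __post_init__(self):
        object.__setattr__(self, "vertices",
                           np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3))
        object.__setattr__(self, "faces",
                           np.asarray(self.faces, dtype=np.int64).reshape(-1, 3))
        object.__setattr__(self, "side", Side(self.side))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unnormalised face normals summed)."""
        fn = self.face_normals(normalize=False)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def signed_volume(self) -> float:
        """Signed volume of the (possibly open) surface via the divergence
        theorem; sign tracks global winding orientation."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return replace(self, vertices=np.asarray(vertices, dtype=np.float64))


@dataclass(frozen=True)
class LandmarkSet:
    """The three named anatomical points of one mesh, in millimetres."""

    mesh_id: str
    points: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        pts = {str(k): np.asarray(v, dtype=np.float64).reshape(3)
               for k, v in self.points.items()}
        object.__setattr__(self, "points", pts)
        missing = [n for n in REQUIRED_LANDMARKS if n not in pts]
        if missing:
            raise SchemaError(
                f"landmark set '{self.mesh_id}' is missing {missing}; "
                f"required names are {list(REQUIRED_LANDMARKS)}")
        extra = [n for n in pts if n not in REQUIRED_LANDMARKS]
        if extra:
            raise SchemaError(
                f"landmark set '{self.mesh_id}' has unexpected names {extra}")
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"landmarks of '{self.mesh_id}' contain non-finite values")
        d01 = np.linalg.norm(arr[0] - arr[1])
        d02 = np.linalg.norm(arr[0] - arr[2])
        d12 = np.linalg.norm(arr[1] - arr[2])
        if min(d01, d02, d12) <= 1e-6:
            raise ValidationError(
                f"landmarks of '{self.mesh_id}' are degenerate: "
                "pairwise distances must exceed 1e-6 mm")
        area = 0.5 * np.linalg.norm(np.cross(arr[1] - arr[0], arr[2] - arr[0]))
        if area <= 1e-9:
            raise ValidationError(
                f"landmarks of '{self.mesh_id}' are collinear (triangle area "
                f"{area:.3g} mm^2 <= 1e-9)")

    def as_array(self) -> np.ndarray:
        """(3, 3) array in canonical landmark order."""
        return np.stack([self.points[n] for n in REQUIRED_LANDMARKS])


# ---------------------------------------------------------------------------
# validation


def _merge_vertices(vertices, faces, tol=MERGE_TOL_MM):
    decimals = max(0, int(round(-np.log10(tol))))
    key = np.round(vertices, decimals)
    # stabilise -0.0 vs 0.0
    key = key + 0.0
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[first]
    # map unique rows back to the order of first occurrence for determinism
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = new_vertices[order]
    new_faces = rank[inverse][faces]
    return new_vertices, new_faces


def _drop_degenerate_faces(vertices, faces):
    if len(faces) == 0:
        return faces, 0
    repeated = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) \
        | (faces[:, 0] == faces[:, 2])
    tri = vertices[faces]
    area2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    degenerate = repeated | (area2 <= 1e-12)
    dropped = int(degenerate.sum())
    return faces[~degenerate], dropped


def _repair_winding(faces):
    """Flip faces until every edge shared by two faces is traversed in
    opposite directions.  Returns (faces, n_flipped, consistent)."""
    if len(faces) == 0:
        return faces, 0, True
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    adjacency: dict[int, list[int]] = {}
    for fs in edge_faces.values():
        if len(fs) == 2:
            a, b = fs
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)

    def directed_edges(f):
        return {(f[0], f[1]), (f[1], f[2]), (f[2], f[0])}

    faces = faces.copy()
    flipped = np.zeros(len(faces), dtype=bool)
    visited = np.zeros(len(faces), dtype=bool)
    n_flipped = 0
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            own = directed_edges(faces[fi])
            for nb in adjacency.get(fi, ()):
                if visited[nb]:
                    continue
                # consistent winding = no directed edge shared
                if own & directed_edges(faces[nb]):
                    faces[nb] = faces[nb][::-1]
                    flipped[nb] = True
                    n_flipped += 1
                visited[nb] = True
                stack.append(nb)
    # verify
    consistent = True
    seen: set[tuple[int, int]] = set()
    for f in faces:
        for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if e in seen:
                consistent = False
                break
            seen.add(e)
    return faces, n_flipped, consistent


def validate_mesh(mesh: TriangleMesh, merge_tol: float = MERGE_TOL_MM,
                  repair_winding: bool = True) -> TriangleMesh:
    """Enforce the TriangleMesh invariants, returning a cleaned mesh.

    Merges duplicate vertices (within ``merge_tol`` mm), drops degenerate
    faces, checks index ranges and finiteness, and repairs face winding so
    adjacent faces agree on orientation.  Idempotent.
    """
    v = np.asarray(mesh.vertices, dtype=np.float64)
    f = np.asarray(mesh.faces, dtype=np.int64)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValidationError(f"mesh '{mesh.id}': vertices must be (n, 3)")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"mesh '{mesh.id}': non-finite vertex coordinates")
    if f.ndim != 2 or f.shape[1] != 3:
        raise ValidationError(f"mesh '{mesh.id}': faces must be (m, 3)")
    if len(f) and (f.min() < 0 or f.max() >= len(v)):
        raise ValidationError(
            f"mesh '{mesh.id}': face index out of range [0, {len(v)})")

    v, f = _merge_vertices(v, f, merge_tol)
    f, dropped = _drop_degenerate_faces(v, f)
    if dropped:
        logger.info("mesh %s: dropped %d degenerate face(s)", mesh.id, dropped)
    # drop unreferenced vertices
    used = np.unique(f) if len(f) else np.array([], dtype=np.int64)
    if len(used) < len(v):
        remap = -np.ones(len(v), dtype=np.int64)
        remap[used] = np.arange(len(used))
        v = v[used]
        f = remap[f] if len(f) else f
    if len(v) < 3 or len(f) < 1:
        raise ValidationError(
            f"mesh '{mesh.id}' is empty after cleaning "
            f"({len(v)} vertices, {len(f)} faces)")
    if repair_winding:
        f, n_flipped, consistent = _repair_winding(f)
        if n_flipped:
            logger.info("mesh %s: flipped %d face(s) for consistent winding",
                        mesh.id, n_flipped)
        if not consistent:
            logger.warning("mesh %s: winding not globally repairable "
                           "(non-manifold edges)", mesh.id)
    return TriangleMesh(id=mesh.id, vertices=v, faces=f, side=mesh.side)


# ---------------------------------------------------------------------------
# STL

_STL_FACET_RE = re.compile(
    r"facet\s+normal\s+(\S+)\s+(\S+)\s+(\S+)\s+outer\s+loop\s+"
    r"vertex\s+(\S+)\s+(\S+)\s+(\S+)\s+"
    r"vertex\s+(\S+)\s+(\S+)\s+(\S+)\s+"
    r"vertex\s+(\S+)\s+(\S+)\s+(\S+)\s+endloop\s+endfacet",
    re.IGNORECASE)


def _read_stl(path: Path):
    raw = path.read_bytes()
    if len(raw) < 15:
        raise MeshFormatError(f"{path}: truncated STL file ({len(raw)} bytes)")
    is_ascii = raw.lstrip()[:5].lower() == b"solid"
    if is_ascii:
        # binary files may also start with 'solid'; check size signature
        if len(raw) >= 84:
            (n,) = struct.unpack_from("<I", raw, 80)
            if len(raw) == 84 + 50 * n and b"facet" not in raw[:200].lower():
                is_ascii = False
    if is_ascii:
        try:
            text = raw.decode("ascii", errors="strict")
        except UnicodeDecodeError as e:
            raise MeshFormatError(f"{path}: not valid ASCII STL") from e
        vals = _STL_FACET_RE.findall(text)
        if not vals:
            raise MeshFormatError(f"{path}: no facets found in ASCII STL")
        arr = np.array(vals, dtype=np.float64)  # (m, 12): normal + 3 vertices
        tri = arr[:, 3:].reshape(-1, 3, 3)
    else:
        if len(raw) < 84:
            raise MeshFormatError(f"{path}: truncated binary STL header")
        (n,) = struct.unpack_from("<I", raw, 80)
        if n == 0:
            raise MeshFormatError(f"{path}: binary STL declares zero facets")
        expected = 84 + 50 * n
        if len(raw) < expected:
            raise MeshFormatError(
                f"{path}: truncated binary STL ({len(raw)} of {expected} bytes)")
        rec = np.frombuffer(raw, dtype=np.dtype([("data", "<12f4"), ("attr", "<u2")]),
                            count=n, offset=84)
        tri = rec["data"].reshape(-1, 4, 3)[:, 1:].astype(np.float64)
    m = len(tri)
    vertices = tri.reshape(-1, 3)
    faces = np.arange(3 * m, dtype=np.int64).reshape(-1, 3)
    return vertices, faces


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    tri = mesh.vertices[mesh.faces].astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if binary:
        with open(path, "wb") as fh:
            fh.write(struct.pack("<80s", b"osteopair binary STL"))
            fh.write(struct.pack("<I", len(tri)))
            rec = np.zeros(len(tri), dtype=np.dtype([("data", "<12f4"), ("attr", "<u2")]))
            rec["data"] = np.concatenate([normals[:, None, :], tri], axis=1).reshape(-1, 12)
            fh.write(rec.tobytes())
    else:
        lines = [f"solid {mesh.id}"]
        for nrm, t in zip(normals, tri):
            lines.append(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.id}\n")
        path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# PLY (ASCII)

_PLY_TYPES = {
    "float": float, "float32": float, "double": float, "float64": float,
    "int": int, "int32": int, "uint": int, "uint32": int,
    "uchar": int, "uint8": int, "char": int, "int8": int,
    "short": int, "ushort": int, "int16": int, "uint16": int,
}


def read_ply(path: Path):
    """Parse an ASCII PLY file.

    Returns ``(vertices, faces, vertex_props)`` where ``vertex_props`` maps
    extra per-vertex property names (e.g. ``quality``, ``red``) to arrays.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}: not a PLY file")
    i = 1
    elements = []  # (name, count, [prop names]), list props marked
    current = None
    fmt = None
    while i < len(lines):
        tok = lines[i].split()
        i += 1
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            current = {"name": tok[1], "count": int(tok[2]), "props": []}
            elements.append(current)
        elif tok[0] == "property":
            if current is None:
                raise MeshFormatError(f"{path}: property before element")
            if tok[1] == "list":
                current["props"].append(("list", tok[-1]))
            else:
                if tok[1] not in _PLY_TYPES:
                    raise MeshFormatError(f"{path}: unsupported PLY type {tok[1]}")
                current["props"].append((tok[1], tok[2]))
        elif tok[0] == "end_header":
            break
    else:
        raise MeshFormatError(f"{path}: missing end_header")
    if fmt != "ascii":
        raise MeshFormatError(f"{path}: only ASCII PLY is supported, got {fmt!r}")

    vertices = np.zeros((0, 3))
    faces = []
    vertex_props: dict[str, list] = {}
    for el in elements:
        rows = lines[i:i + el["count"]]
        if len(rows) < el["count"]:
            raise MeshFormatError(f"{path}: truncated PLY element {el['name']}")
        i += el["count"]
        if el["name"] == "vertex":
            names = [p[1] for p in el["props"]]
            data = np.array([r.split() for r in rows], dtype=np.float64)
            if data.shape[1] != len(names):
                raise MeshFormatError(f"{path}: vertex row width mismatch")
            cols = {n: data[:, k] for k, n in enumerate(names)}
            for ax in "xyz":
                if ax not in cols:
                    raise MeshFormatError(f"{path}: vertex missing '{ax}'")
            vertices = np.column_stack([cols["x"], cols["y"], cols["z"]])
            vertex_props = {n: cols[n] for n in names if n not in ("x", "y", "z")}
        elif el["name"] == "face":
            for r in rows:
                tok = r.split()
                cnt = int(tok[0])
                if cnt != 3:
                    raise MeshFormatError(f"{path}: only triangular faces supported")
                faces.append([int(t) for t in tok[1:4]])
    return vertices, np.asarray(faces, dtype=np.int64).reshape(-1, 3), vertex_props


def write_ply(path: Path, vertices: np.ndarray, faces: np.ndarray,
              quality: np.ndarray | None = None,
              rgb: np.ndarray | None = None) -> None:
    """Write an ASCII PLY, optionally with per-vertex quality scalar and
    uchar RGB colour (the chromatic-map payload)."""
    path = Path(path)
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    header = ["ply", "format ascii 1.0", f"element vertex {len(v)}",
              "property double x", "property double y", "property double z"]
    if quality is not None:
        header.append("property double quality")
    if rgb is not None:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header += [f"element face {len(f)}",
               "property list uchar int vertex_indices", "end_header"]
    rows = []
    for k in range(len(v)):
        parts = [f"{v[k, 0]:.12g}", f"{v[k, 1]:.12g}", f"{v[k, 2]:.12g}"]
        if quality is not None:
            parts.append(f"{quality[k]:.12g}")
        if rgb is not None:
            parts += [str(int(rgb[k, 0])), str(int(rgb[k, 1])), str(int(rgb[k, 2]))]
        rows.append(" ".join(parts))
    for fc in f:
        rows.append(f"3 {fc[0]} {fc[1]} {fc[2]}")
    path.write_text("\n".join(header + rows) + "\n")


# ---------------------------------------------------------------------------
# public mesh API


def read_mesh(path, expected_units: str = "mm", mesh_id: str | None = None,
              side: Side | str = Side.UNKNOWN) -> TriangleMesh:
    """Read an STL (ASCII or binary) or ASCII PLY mesh and validate it.

    ``expected_units`` must be ``"mm"``: the formats carry no unit metadata
    and every downstream quantity (RMS, thresholds) is in millimetres.
    """
    if expected_units != "mm":
        raise ValidationError(f"unsupported units {expected_units!r}; only 'mm'")
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"{path}: no such file")
    ext = path.suffix.lower()
    if ext == ".stl":
        vertices, faces = _read_stl(path)
    elif ext == ".ply":
        vertices, faces, _ = read_ply(path)
    else:
        raise MeshFormatError(f"{path}: unsupported extension {ext!r} "
                              "(expected .stl or .ply)")
    mesh = TriangleMesh(id=mesh_id or path.stem, vertices=vertices, faces=faces,
                        side=Side(side))
    return validate_mesh(mesh)


def write_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a mesh as ``stl_binary`` (default for .stl), ``stl_ascii`` or
    ``ply``.  STL stores float32, so coordinates round-trip to ~1e-6
    relative precision only."""
    path = Path(path)
    if format is None:
        format = {"stl": "stl_binary", "ply": "ply"}.get(path.suffix.lower().lstrip("."))
    if format == "stl_binary":
        _write_stl(mesh, path, binary=True)
    elif format == "stl_ascii":
        _write_stl(mesh, path, binary=False)
    elif format == "ply":
        write_ply(path, mesh.vertices, mesh.faces)
    else:
        raise ValidationError(f"unknown mesh format {format!r}")


def read_landmarks(path) -> LandmarkSet:
    """Read the landmark sidecar JSON
    ``{"mesh_id": ..., "landmarks": {"sym_sup": [x,y,z], ...}}``."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: invalid JSON: {e}") from e
    if not isinstance(doc, dict) or "landmarks" not in doc:
        raise SchemaError(f"{path}: missing 'landmarks' object")
    lm = doc["landmarks"]
    missing = [n for n in REQUIRED_LANDMARKS if n not in lm]
    if missing:
        raise SchemaError(f"{path}: missing landmark(s) {missing}")
    return LandmarkSet(mesh_id=str(doc.get("mesh_id", path.stem)), points=lm)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    doc = {"mesh_id": landmarks.mesh_id,
           "landmarks": {k: [float(x) for x in v]
                         for k, v in landmarks.points.items()}}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
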