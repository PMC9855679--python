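"""Point-to-surface distance fields, the RMS similarity statistic, and
chromatic-map export.

The similarity proxy between a registered (mirrored-left) model and the
fixed right model is the RMS of per-vertex distances from the moving model
to the fixed surface: squaring prevents receding (negative) and prominent
(positive) regions from cancelling, unlike a signed arithmetic mean.

The chromatic map writes signed distance per vertex into a PLY with a
diverging colour code — blue for receding areas, green where the surfaces
coincide, through yellow/orange to red for prominent areas.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._surface import SurfaceQuery
from .errors import ValidationError
from .mesh_io import TriangleMesh, write_ply

DEFAULT_COLOR_RANGE_MM = 2.0


@dataclass(frozen=True)
class DistanceField:
    """Per-vertex distances from a source mesh to a target surface (mm).

    ``signed_distances`` carries orientation: positive where the source
    vertex lies outside the target surface along its interpolated normal
    (prominent), negative inside (receding).  Magnitudes equal
    ``distances`` exactly.
    """

    source_mesh_id: str
    target_mesh_id: str
    distances: np.ndarray
    signed_distances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=np.float64).reshape(-1)
        s = np.asarray(self.signed_distances, dtype=np.float64).reshape(-1)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "signed_distances", s)
        if len(d) == 0:
            raise ValidationError("empty distance field")
        if len(d) != len(s):
            raise ValidationError("distances and signed_distances differ in length")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValidationError("unsigned distances must be finite and >= 0")
        if not np.allclose(np.abs(s), d, atol=1e-9):
            raise ValidationError("|signed_distances| must equal distances")

    def __len__(self) -> int:
        return len(self.distances)


def surface_distances(source: TriangleMesh, target: TriangleMesh,
                      mode: str = "surface",
                      surface_query: SurfaceQuery | None = None) -> DistanceField:
    """Distance from every source vertex to the target surface.

    ``source`` must already be registered onto ``target``; no transform is
    applied here.  ``mode="surface"`` (default) projects onto the target
    triangulation; ``mode="vertex"`` uses nearest target vertices.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValidationError("cannot compute distances for empty meshes")
    if mode not in ("surface", "vertex"):
        raise ValidationError(f"unknown distance mode {mode!r}")
    query = surface_query or SurfaceQuery(target)
    pts = source.vertices
    if mode == "surface":
        res = query.closest(pts)
        normals = query.interpolated_normals(res.face, res.bary)
        offset = pts - res.point
        d = res.distance
    else:
        d, vidx = query.closest_vertices(pts)
        normals = query.vertex_normals[vidx]
        offset = pts - target.vertices[vidx]
    sign = np.where(np.einsum("ij,ij->i", offset, normals) < 0, -1.0, 1.0)
    return DistanceField(source_mesh_id=source.id, target_mesh_id=target.id,
                         distances=d, signed_distances=sign * d)


def rms(field) -> float:
    """Root-mean-square distance: ``sqrt(mean(d_i^2))`` over unsigned
    distances (mm).  Accepts a :class:`DistanceField` or a plain array."""
    d = field.distances if isinstance(field, DistanceField) else \
        np.asarray(field, dtype=np.float64).reshape(-1)
    if len(d) == 0:
        raise ValidationError("rms of an empty distance field is undefined")
    return float(np.sqrt(np.mean(np.square(np.abs(d)))))


def diverging_rgb(x: np.ndarray) -> np.ndarray:
    """Map values in [-1, 1] to the blue→green→red diverging colour code
    used by the chromatic maps (uint8 RGB)."""
    x = np.clip(np.asarray(x, dtype=np.float64), -1.0, 1.0)
    rgb = np.zeros((len(x), 3))
    neg = x < 0
    t = x + 1.0          # [0, 1] on the negative side
    rgb[neg, 1] = t[neg]
    rgb[neg, 2] = 1.0 - t[neg]
    rgb[~neg, 0] = x[~neg]
    rgb[~neg, 1] = 1.0 - x[~neg]
    return np.round(255 * rgb).astype(np.uint8)


def write_distance_map(source: TriangleMesh, field: DistanceField, path,
                       color_range: float = DEFAULT_COLOR_RANGE_MM) -> None:
    """Write the chromatic map: an ASCII PLY of the source mesh with
    per-vertex ``quality`` = signed distance (mm) and diverging RGB colour,
    clipped at ``±color_range``."""
    if len(field) != source.n_vertices:
        raise ValidationError(
            f"distance field length {len(field)} != source vertex count "
            f"{source.n_vertices}")
    if not color_range > 0:
        raise ValidationError("color_range must be > 0")
    rgb = diverging_rgb(field.signed_distances / color_range)
    write_ply(path, source.vertices, source.faces,
              quality=field.signed_distances, rgb=rgb)


def write_distance_csv(field: DistanceField, path) -> None:
    """CSV export of per-vertex signed distances (vertex_index, d_signed_mm)."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_index", "d_signed_mm"])
        for i, d in enumerate(field.signed_distances):
            w.writerow([i, f"{d:.9g}"])
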