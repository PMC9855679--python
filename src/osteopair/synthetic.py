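"""Synthetic assemblages of left/right bone-like shells with ground truth.

Real pubic-bone models cannot be redistributed, so tests and demonstrations
run on generated assemblages that emulate the *variance structure* that
drives pair-matching rather than pubic anatomy itself: bilateral asymmetry
within an individual (``sigma_asym``) is small relative to shape variation
between individuals (``sigma_between``).

Each individual starts from a shared template — a curved, plate-like open
shell roughly 40×30×15 mm with a foramen-like notch — deformed by a smooth
random field common to both sides (the individual's shape), with the right
side additionally deformed by an independent smooth field (its asymmetry).
The left element is the mirror image of the individual's shape, as a left
bone is of a right one.  Three template vertices are tracked through the
deformations and serve as the anatomical landmarks.

Defaults follow the reference sampling design: 20 paired individuals plus
2 unpaired lefts per group, two groups — 880 within-group superimpositions,
40 matches, 840 mismatches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .mesh_io import (LandmarkSet, Side, TriangleMesh, validate_mesh,
                      write_landmarks, write_mesh)
from .mesh_ops import mirror_landmarks, mirror_mesh


@dataclass(frozen=True)
class AssemblageConfig:
    """Generator settings.

    sigma_between and sigma_asym are RMS displacement amplitudes in mm of
    the smooth deformation fields; mesh_subdivisions doubles the template
    grid per level (0 ≈ 170 vertices, enough to resolve the deformation
    wavelengths while keeping an 880-superimposition run fast).
    """

    n_paired: int = 20
    n_unpaired_left: int = 2
    groups: tuple = ("males", "females")
    sigma_between: float = 2.0     # mm, between-individual shape variation
    sigma_asym: float = 0.3        # mm, within-individual bilateral asymmetry
    mesh_subdivisions: int = 0
    pose_randomisation: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_paired < 1:
            raise ValidationError("n_paired must be >= 1")
        if self.n_unpaired_left < 0:
            raise ValidationError("n_unpaired_left must be >= 0")
        if self.sigma_between < 0 or self.sigma_asym < 0:
            raise ValidationError("deformation amplitudes must be >= 0")
        if self.mesh_subdivisions < 0:
            raise ValidationError("mesh_subdivisions must be >= 0")
        if not self.groups:
            raise ValidationError("at least one group is required")


# ---------------------------------------------------------------------------
# primitives


def uv_sphere(radius: float = 10.0, n_theta: int = 12, n_phi: int = 18,
              center=(0.0, 0.0, 0.0), mesh_id: str = "sphere") -> TriangleMesh:
    """A closed UV sphere mesh with outward-wound faces (test primitive)."""
    theta = np.linspace(0, np.pi, n_theta + 1)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    verts = [(0.0, 0.0, radius)]
    for t in theta[1:-1]:
        for p in phi:
            verts.append((radius * np.sin(t) * np.cos(p),
                          radius * np.sin(t) * np.sin(p),
                          radius * np.cos(t)))
    verts.append((0.0, 0.0, -radius))
    v = np.asarray(verts) + np.asarray(center)

    faces = []
    def ring(i):            # vertex index of ring i (1..n_theta-1), col j
        return lambda j: 1 + (i - 1) * n_phi + (j % n_phi)
    # top cap
    r1 = ring(1)
    for j in range(n_phi):
        faces.append((0, r1(j), r1(j + 1)))
    # body
    for i in range(1, n_theta - 1):
        ra, rb = ring(i), ring(i + 1)
        for j in range(n_phi):
            faces.append((ra(j), rb(j), rb(j + 1)))
            faces.append((ra(j), rb(j + 1), ra(j + 1)))
    # bottom cap
    last = len(v) - 1
    rl = ring(n_theta - 1)
    for j in range(n_phi):
        faces.append((rl(j), last, rl(j + 1)))
    return validate_mesh(TriangleMesh(id=mesh_id, vertices=v, faces=faces))


def _template(subdivisions: int):
    """The shared shell template.

    Returns (vertices, faces, landmark_indices) where landmark_indices maps
    the three canonical landmark names to template vertex indices.  The
    shell is a curved plate z = f(u, v) over [0,1]² with an elliptical hole
    (the foramen-like notch); landmarks sit at the superior and inferior
    medial edge (symphysis stand-ins) and on the medial rim of the notch.
    """
    nu = 16 * 2 ** subdivisions + 1
    nv = 12 * 2 ** subdivisions + 1
    u, v = np.meshgrid(np.linspace(0, 1, nu), np.linspace(0, 1, nv),
                       indexing="ij")
    x = 40.0 * u - 20.0
    y = 30.0 * v - 15.0
    z = 15.0 * np.sin(np.pi * np.clip(u, 0, 1)) * np.sin(np.pi * np.clip(v, 0, 1))
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    uu, vv = u.ravel(), v.ravel()

    in_hole = (((uu - 0.68) / 0.16) ** 2 + ((vv - 0.34) / 0.18) ** 2) < 1.0
    keep = ~in_hole
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[keep] = np.arange(keep.sum())

    def vid(i, j):
        return i * nv + j

    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            q = [vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)]
            if all(keep[k] for k in q):
                faces.append((remap[q[0]], remap[q[1]], remap[q[2]]))
                faces.append((remap[q[0]], remap[q[2]], remap[q[3]]))
    vertices = pts[keep]
    uk, vk = uu[keep], vv[keep]

    def nearest(ut, vt):
        return int(np.argmin((uk - ut) ** 2 + (vk - vt) ** 2))

    landmarks = {"sym_sup": nearest(0.06, 0.88),
                 "sym_inf": nearest(0.06, 0.12),
                 "obt_med": nearest(0.49, 0.34)}
    return vertices, np.asarray(faces, dtype=np.int64), landmarks


def _smooth_field(points: np.ndarray, rng: np.random.Generator,
                  sigma: float, n_basis: int = 10,
                  length_scale: float = 25.0) -> np.ndarray:
    """Smooth random displacement field: a sum of low-frequency trigonometric
    plane waves, rescaled so the RMS displacement magnitude over the given
    points equals ``sigma`` (mm).  Wavelengths ≥ ~17 mm at the default
    length scale keep the shells self-intersection-free at the default
    amplitudes."""
    disp = np.zeros_like(points)
    for _ in range(n_basis):
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        freq = rng.uniform(0.5, 1.5) / length_scale      # cycles per mm
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.normal(size=3)
        disp += amp * np.sin(2 * np.pi * freq * (points @ w) + phase)[:, None]
    if sigma == 0:
        return np.zeros_like(points)
    scale = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    if scale == 0:
        return np.zeros_like(points)
    return disp * (sigma / scale)


def _random_pose(rng: np.random.Generator):
    """Uniform random rotation (normalised quaternion) + translation."""
    from scipy.spatial.transform import Rotation
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    r = Rotation.from_quat(q).as_matrix()
    t = rng.uniform(-25.0, 25.0, size=3)
    return r, t


@dataclass(frozen=True)
class Individual:
    id: str
    group: str
    left: TriangleMesh
    right: TriangleMesh | None
    left_landmarks: LandmarkSet
    right_landmarks: LandmarkSet | None
    paired: bool = True

    def without_right(self) -> "Individual":
        """The unpaired-left variant: the right element is withheld."""
        return replace(self, right=None, right_landmarks=None, paired=False)


def generate_individual(seed, config: AssemblageConfig,
                        individual_id: str = "ind",
                        group: str = "group") -> Individual:
    """Generate one individual's left and right elements with landmarks.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  With
    ``sigma_asym = 0`` and pose randomisation off, the mirrored left equals
    the right exactly.
    """
    rng = np.random.default_rng(seed)
    v0, faces, lm_idx = _template(config.mesh_subdivisions)

    shape = v0 + _smooth_field(v0, rng, config.sigma_between)
    asym = _smooth_field(v0, rng, config.sigma_asym)
    right_v = shape + asym

    right = TriangleMesh(id=f"{individual_id}_right", vertices=right_v,
                         faces=faces, side=Side.RIGHT)
    left_shape = TriangleMesh(id=f"{individual_id}_left", vertices=shape,
                              faces=faces, side=Side.RIGHT)
    left = mirror_mesh(left_shape, plane="x")     # left = mirror of the shape

    def lm_from(verts, mesh_id):
        return LandmarkSet(mesh_id=mesh_id,
                           points={n: verts[i] for n, i in lm_idx.items()})

    right_lm = lm_from(right_v, right.id)
    left_lm = mirror_landmarks(lm_from(shape, left.id), plane="x")

    if config.pose_randomisation:
        for which in ("left", "right"):
            r, t = _random_pose(rng)
            if which == "left":
                left = left.with_vertices(left.vertices @ r.T + t)
                left_lm = LandmarkSet(left_lm.mesh_id,
                                      {n: r @ p + t for n, p in left_lm.points.items()})
            else:
                right = right.with_vertices(right.vertices @ r.T + t)
                right_lm = LandmarkSet(right_lm.mesh_id,
                                       {n: r @ p + t for n, p in right_lm.points.items()})
    return Individual(id=individual_id, group=group, left=left, right=right,
                      left_landmarks=left_lm, right_landmarks=right_lm)


@dataclass(frozen=True)
class Assemblage:
    """An in-memory assemblage: individuals per group plus ground truth."""

    config: AssemblageConfig
    individuals: tuple = field(default_factory=tuple)

    def group_members(self, group: str) -> list:
        return [ind for ind in self.individuals if ind.group == group]

    @property
    def truth(self) -> set:
        return {(ind.left.id, ind.right.id)
                for ind in self.individuals if ind.paired}

    @property
    def n_comparisons(self) -> int:
        total = 0
        for g in self.config.groups:
            members = self.group_members(g)
            total += len(members) * sum(m.paired for m in members)
        return total


def generate_assemblage(config: AssemblageConfig,
                        out_dir: str | Path | None = None) -> Assemblage:
    """Generate the full assemblage; optionally write it to ``out_dir`` as
    ``meshes/{id}_{side}.stl``, ``landmarks/{id}_{side}.json``, ``truth.csv``
    and ``manifest.json`` (with file checksums).

    A single master seed spawns one child seed per individual, so the
    assemblage is reproducible as a whole while individuals stay
    independent.
    """
    ss = np.random.SeedSequence(config.seed)
    per_group = config.n_paired + config.n_unpaired_left
    children = ss.spawn(per_group * len(config.groups))

    individuals = []
    k = 0
    for group in config.groups:
        prefix = group[:1]
        for i in range(per_group):
            ind = generate_individual(children[k], config,
                                      individual_id=f"{prefix}{i + 1:02d}",
                                      group=group)
            if i >= config.n_paired:
                ind = ind.without_right()
            individuals.append(ind)
            k += 1
    asm = Assemblage(config=config, individuals=tuple(individuals))
    if out_dir is not None:
        write_assemblage(asm, out_dir)
    return asm


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_assemblage(asm: Assemblage, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)
    files = []
    for ind in asm.individuals:
        items = [(ind.left, ind.left_landmarks)]
        if ind.paired:
            items.append((ind.right, ind.right_landmarks))
        for mesh, lm in items:
            mp = out / "meshes" / f"{mesh.id}.stl"
            write_mesh(mesh, mp, format="stl_binary")
            lp = out / "landmarks" / f"{mesh.id}.json"
            write_landmarks(lm, lp)
            files += [mp, lp]
    truth_lines = ["left_id,right_id"]
    truth_lines += [f"{left},{right}" for left, right in sorted(asm.truth)]
    (out / "truth.csv").write_text("\n".join(truth_lines) + "\n")

    cfg = asm.config
    manifest = {
        "config": {"n_paired": cfg.n_paired,
                   "n_unpaired_left": cfg.n_unpaired_left,
                   "groups": list(cfg.groups),
                   "sigma_between": cfg.sigma_between,
                   "sigma_asym": cfg.sigma_asym,
                   "mesh_subdivisions": cfg.mesh_subdivisions,
                   "pose_randomisation": cfg.pose_randomisation,
                   "seed": cfg.seed},
        "individuals": [{"id": ind.id, "group": ind.group, "paired": ind.paired}
                        for ind in asm.individuals],
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True) + "\n")
    return out
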