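"""Rigid registration: landmark-seeded coarse alignment + ICP refinement.

The protocol registers the mirrored left bone onto the right bone in two
stages, exactly rigid throughout (rotation + translation; shape only, never
scale):

1. **Landmark alignment** — least-squares rigid fit (Kabsch) over the three
   named anatomical landmarks, giving a coarse starting pose.
2. **ICP** — iterate nearest-point correspondence from each moving vertex to
   the fixed triangulated surface and a closed-form rigid update, until the
   RMS improvement drops below tolerance.

The correspondence target defaults to the nearest point *on* the fixed
surface (point-to-triangle projection), which is resolution independent;
nearest-vertex mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from ._surface import SurfaceQuery
from .errors import ValidationError
from .mesh_io import LandmarkSet, TriangleMesh

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x ↦ R x + t`` (det R = +1, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(t)):
            raise ValidationError("rigid transform contains non-finite values")
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise ValidationError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=_ORTHO_TOL):
            raise ValidationError(
                "rotation determinant != +1 (reflection or scale is not rigid)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first.  The product rotation is
        re-projected onto SO(3) so orthonormality cannot drift over many
        ICP compositions."""
        r = Rotation.from_matrix(self.rotation @ other.rotation).as_matrix()
        t = self.rotation @ other.translation + self.translation
        return RigidTransform(r, t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass(frozen=True)
class ICPParams:
    """ICP controls.

    The reference protocol's fine-registration internals are proprietary;
    these defaults refine to numerical convergence on whole surfaces with no
    correspondence trimming, which is the closest published reading of it.
    """

    max_iterations: int = 100
    rms_change_tolerance: float = 1e-6     # mm
    max_correspondence_distance: float = np.inf   # mm; inf = no trimming
    sample_size: int | None = None         # None = all moving vertices

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not self.rms_change_tolerance > 0:
            raise ValidationError("rms_change_tolerance must be > 0")
        if self.sample_size is not None and self.sample_size < 3:
            raise ValidationError("sample_size must be >= 3")


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    iterations_run: int
    converged: bool
    final_rms: float                       # mm
    rms_trajectory: np.ndarray = field(repr=False, default=None)


def kabsch(moving: np.ndarray, fixed: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``moving`` onto
    ``fixed`` (paired points).  Reflections are excluded by construction,
    so degenerate configurations that would prefer det = −1 return the best
    proper rotation with nonzero residual instead."""
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValidationError("kabsch needs matched (n, 3) point sets")
    if len(moving) < 3:
        raise ValidationError("kabsch needs at least 3 correspondences")
    w = None if weights is None else np.asarray(weights, dtype=np.float64)
    cm = np.average(moving, axis=0, weights=w)
    cf = np.average(fixed, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(fixed - cf, moving - cm, weights=w)
    r = rot.as_matrix()
    return RigidTransform(r, cf - r @ cm)


def landmark_align(moving_lm: LandmarkSet, fixed_lm: LandmarkSet) -> RigidTransform:
    """Coarse alignment: Kabsch over the three named landmarks, matched by
    name.  Both sets must carry the full canonical landmark names (enforced
    by :class:`LandmarkSet`)."""
    return kabsch(moving_lm.as_array(), fixed_lm.as_array())


def landmark_residual_rms(transform: RigidTransform, moving_lm: LandmarkSet,
                          fixed_lm: LandmarkSet) -> float:
    """RMS distance between transformed moving landmarks and fixed ones."""
    d = transform.apply(moving_lm.as_array()) - fixed_lm.as_array()
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def icp_register(moving: TriangleMesh, fixed: TriangleMesh,
                 init: RigidTransform | None = None,
                 params: ICPParams | None = None,
                 correspondence: str = "surface",
                 surface_query: SurfaceQuery | None = None) -> RegistrationResult:
    """Refine a rigid registration of ``moving`` onto ``fixed`` by ICP.

    Each iteration finds, for every (sampled) moving vertex at its current
    pose, the closest point on the fixed surface, then applies the
    closed-form rigid update.  Stops when the RMS decrease falls below
    ``params.rms_change_tolerance`` or after ``params.max_iterations``;
    non-convergence is reported via ``converged=False``, not raised.

    The per-iteration RMS trajectory is non-increasing: the rigid update
    cannot increase the distance to the current correspondences, and the
    surface distance is bounded by the distance to any surface point.
    """
    if moving.n_vertices == 0 or fixed.n_vertices == 0:
        raise ValidationError("cannot register empty meshes")
    if correspondence not in ("surface", "vertex"):
        raise ValidationError(f"unknown correspondence mode {correspondence!r}")
    params = params or ICPParams()
    init = init or RigidTransform.identity()
    query = surface_query or SurfaceQuery(fixed)

    pts = moving.vertices
    if params.sample_size is not None and params.sample_size < len(pts):
        # deterministic, evenly spread subsample
        idx = np.linspace(0, len(pts) - 1, params.sample_size).round().astype(int)
        pts = pts[np.unique(idx)]

    rot = init.rotation.copy()
    tra = init.translation.copy()
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        cur = pts @ rot.T + tra
        if correspondence == "surface":
            res = query.closest(cur)
            d, targets = res.distance, res.point
        else:
            d, vidx = query.closest_vertices(cur)
            targets = fixed.vertices[vidx]
        if np.isfinite(params.max_correspondence_distance):
            keep = d <= params.max_correspondence_distance
            if keep.sum() < 3:
                keep = np.ones(len(d), dtype=bool)
            cur_k, targets_k = cur[keep], targets[keep]
        else:
            cur_k, targets_k = cur, targets
        rms = float(np.sqrt(np.mean(d ** 2)))
        trajectory.append(rms)
        if len(trajectory) >= 2 and trajectory[-2] - rms < params.rms_change_tolerance:
            converged = True
            break
        if it == params.max_iterations:
            break
        # closed-form rigid update (Kabsch, proper rotation forced), composed
        # in raw arrays; the step rotation comes from an SVD so orthonormality
        # cannot drift across iterations
        cm = cur_k.mean(axis=0)
        cf = targets_k.mean(axis=0)
        u, _, vt = np.linalg.svd((cur_k - cm).T @ (targets_k - cf))
        sign = np.sign(np.linalg.det(vt.T @ u.T))
        step_rot = (vt.T * np.array([1.0, 1.0, sign])) @ u.T
        rot = step_rot @ rot
        tra = step_rot @ tra + (cf - step_rot @ cm)

    transform = RigidTransform(rot, tra)
    return RegistrationResult(transform=transform, iterations_run=it,
                              converged=converged, final_rms=trajectory[-1],
                              rms_trajectory=np.asarray(trajectory))


class RigidRegistration(BaseEstimator):
    """Landmark-seeded rigid ICP registration, estimator-style.

    Parameters
    ----------
    max_iterations : int
        ICP iteration cap.
    tol_mm : float
        Stop when the per-iteration RMS decrease falls below this (mm).
    max_correspondence_distance : float
        Correspondences farther than this are dropped from the update
        (default: no trimming, whole surfaces).
    sample_size : int or None
        Moving-vertex subsample for the update; None uses all vertices.
    correspondence : {"surface", "vertex"}
        Nearest point on the fixed surface vs nearest fixed vertex.

    Attributes
    ----------
    transform_ : RigidTransform
        The fitted rigid map (includes the landmark initialisation).
    rms_ : float
        Final RMS point-to-surface distance, mm.
    rms_trajectory_ : ndarray
        Per-iteration RMS, non-increasing.
    n_iter_ : int
    converged_ : bool
    landmark_residual_rms_ : float or None
        Residual of the coarse landmark fit, when landmarks were given.
    """

    def __init__(self, max_iterations: int = 100, tol_mm: float = 1e-6,
                 max_correspondence_distance: float = np.inf,
                 sample_size: int | None = None,
                 correspondence: str = "surface"):
        self.max_iterations = max_iterations
        self.tol_mm = tol_mm
        self.max_correspondence_distance = max_correspondence_distance
        self.sample_size = sample_size
        self.correspondence = correspondence

    def fit(self, moving: TriangleMesh, fixed: TriangleMesh,
            moving_landmarks: LandmarkSet | None = None,
            fixed_landmarks: LandmarkSet | None = None,
            init: RigidTransform | None = None,
            surface_query: SurfaceQuery | None = None) -> "RigidRegistration":
        if init is None and moving_landmarks is not None and fixed_landmarks is not None:
            init = landmark_align(moving_landmarks, fixed_landmarks)
            self.landmark_residual_rms_ = landmark_residual_rms(
                init, moving_landmarks, fixed_landmarks)
        else:
            self.landmark_residual_rms_ = None
        params = ICPParams(max_iterations=self.max_iterations,
                           rms_change_tolerance=self.tol_mm,
                           max_correspondence_distance=self.max_correspondence_distance,
                           sample_size=self.sample_size)
        res = icp_register(moving, fixed, init=init, params=params,
                           correspondence=self.correspondence,
                           surface_query=surface_query)
        self.transform_ = res.transform
        self.rotation_ = res.transform.rotation
        self.translation_ = res.transform.translation
        self.rms_ = res.final_rms
        self.rms_trajectory_ = res.rms_trajectory
        self.n_iter_ = res.iterations_run
        self.converged_ = res.converged
        return self

    def transform(self, X):
        """Apply the fitted rigid map to an (n, 3) point array or a
        :class:`TriangleMesh`."""
        if not hasattr(self, "transform_"):
            raise ValidationError("RigidRegistration is not fitted")
        if isinstance(X, TriangleMesh):
            return X.with_vertices(self.transform_.apply(X.vertices))
        return self.transform_.apply(X)
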