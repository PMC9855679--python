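# Methods

## Problem and model

Sorting commingled skeletal remains requires deciding whether a left and a
right bilateral element (here: pubic-bone-like surface models) come from
the same individual. The quantity this package computes is the residual
shape difference after the best rigid superimposition of the mirrored left
model onto the right model:

1. **Mirroring.** The left mesh is reflected across a coordinate plane
   (default `x = 0`) with its face winding reversed so outward orientation
   is preserved. The choice of plane is immaterial — any two reflections
   differ by a rigid motion, which the registration absorbs.
2. **Coarse alignment.** Three named anatomical landmarks (`sym_sup`,
   `sym_inf`, `obt_med`: the superior and inferior points of the pubic
   symphysis and the most medial point of the obturator foramen) are
   aligned by the least-squares rigid (Kabsch) fit. Reflections are
   excluded by construction: three points are always coplanar, so a proper
   rotation always attains the optimum for landmark triplets.
3. **ICP refinement.** Iterate (a) for every moving vertex, the closest
   point on the fixed triangulated surface, (b) the closed-form rigid
   update on those correspondences. Rotation + translation only; no
   scaling at any stage — the statistic measures shape difference, and a
   scale degree of freedom would absorb size differences between
   individuals that carry discriminating signal.
4. **Similarity statistic.** RMS of the per-vertex distances from the
   registered (mirrored-left) model to the fixed right surface,
   `sqrt(mean d_i^2)` in mm. Squaring prevents receding (negative) and
   prominent (positive) regions from cancelling, unlike a signed mean.
5. **Classification.** In an all-against-all design within a group, a cell
   is predicted a match when its RMS does not exceed a threshold. The rule
   is *inclusive* (`rms <= t`): in the reference data the largest match RMS
   equals the operating threshold while sensitivity is 100%, which is only
   consistent if a match exactly at the threshold counts as detected.
   `sweep_thresholds` evaluates every observed RMS value as a threshold and
   recommends the largest threshold with zero false negatives and minimal
   false positives (the max-match-RMS choice whenever matches are the
   lowest values).

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `ICPParams.max_iterations` | 100 | – | ample for convergence from a landmark start |
| `ICPParams.rms_change_tolerance` | 1e-6 | mm | numerical convergence; far below any biological signal |
| `ICPParams.max_correspondence_distance` | ∞ | mm | whole surfaces, no trimming — the protocol uses complete models |
| `ICPParams.sample_size` | all vertices | – | no subsampling below ~100k vertices |
| mirror plane | `x = 0` | – | arbitrary; absorbed by registration (tested) |
| `hollow_mesh.n_directions` | 256 | – | viewpoint budget; see below |
| `hollow_mesh.offset_factor` | 1.5 | – | viewpoints safely outside the bounding sphere |
| `write_distance_map.color_range` | 2.0 | mm | covers the observed match/mismatch RMS range |

The reference implementation of the fine registration (a commercial
package) does not publish its algorithm, stopping rule or sampling; the ICP
defaults above are reasoned substitutes exposed as configuration, not
asserted as equivalent.

## Numerical choices

- **Closest point on surface.** Exact point-to-triangle projection
  (Ericson region classification), accelerated either by a compiled brute
  force kernel over all faces (numba, used for meshes up to 20k faces) or,
  as fallback, a KD-tree over face centroids with a provable certification
  bound: a missed triangle would need its centroid within
  `d_best + r_max` of the query, `r_max` being the largest
  centroid-to-vertex distance; uncertified points re-test every face. Both
  paths are exact and agree with an independent enumeration oracle to
  1e-9 mm in the tests.
- **Ties.** Queries at exactly equal distance resolve to the lowest face
  index (candidates scanned in ascending face order), making results
  deterministic across runs.
- **Rigidity.** Every ICP step rotation comes from an SVD, so orthonormal
  drift cannot accumulate; the final transform is validated
  (`RᵀR = I`, `det R = +1`, tolerance 1e-8) and tests assert 1e-9.
- **Monotone trajectory.** The per-iteration RMS never increases: the
  rigid update cannot increase distances to the current correspondence
  points, and the surface distance is bounded by the distance to any point
  of the surface.
- **Distance sign.** Positive = source vertex outside the target surface
  along the barycentric interpolation of area-weighted vertex normals at
  the closest point; zero distances take positive sign. RMS is
  sign-independent by construction, so the convention affects chromatic
  maps only.
- **Vertex merge.** STL duplicates vertices per facet; reading merges
  coordinates equal after rounding at 1e-9 mm and drops zero-area facets.
  Winding consistency is restored by flipping faces along a spanning
  traversal of the face adjacency graph (non-manifold edges are left
  untouched with a warning).
- **Mann–Whitney.** Exact null when the combined sample is ≤ 20 and
  tie-free, otherwise the normal approximation with tie correction (both
  via scipy); two-sided p-values.
- **TEM/rTEM.** `TEM = sqrt(Σ d² / 2n)` over paired repeated measurements;
  `rTEM = 100·TEM / grand mean of all 2n values` (the standard
  anthropometric denominator). Qualitative rating bands are a configurable
  argument, not hard-coded.
- **Rounding.** Sensitivity/specificity are reported as percentages
  rounded to one decimal; raw fractions are kept alongside in the
  machine-readable report.

## Hollowing

Segmented bone models retain interior (trabecular) geometry that distorts
surface registration. `hollow_mesh` reimplements visibility-based interior
removal: viewpoints sit on a sphere of 1.5× the bounding-sphere radius at
quasi-uniform positions from a *nested* low-discrepancy sequence (Halton
bases 2/3 mapped area-preservingly to the sphere), and a face is kept when
any of its three vertices or its centroid can be reached from some
viewpoint by an unblocked segment (Möller–Trumbore occlusion test).
Conservative retention (partial occlusion keeps the face) avoids punching
holes in the outer shell. Because viewpoint sets are nested, increasing
`n_directions` can only reveal more faces — hollowing is monotone and
idempotent. Whether the original tool removes faces or whole connected
components is unknown; face-level removal is the default and
`mode="component"` keeps every component containing a visible face.

## Synthetic assemblages

The generator emulates the *variance structure* of bilateral bones, not
pubic anatomy: a shared template (a curved open shell ~40×30×15 mm with an
elliptical notch standing in for the obturator foramen, ~200 vertices at
`mesh_subdivisions=0`) is deformed per individual by a smooth random field
(sum of 10 low-frequency trigonometric plane waves, RMS amplitude
`sigma_between = 2.0 mm`), the right side additionally by an independent
field of amplitude `sigma_asym = 0.3 mm`, and the left element is the
mirror image of the individual's shape. Landmarks are three fixed template
vertices tracked through the deformation; random rigid poses are applied
per side by default. A master seed spawns per-individual seed sequences,
so assemblages are reproducible while individuals stay independent.

With these defaults the within-pair signal (`sigma_asym`) is an order of
magnitude smaller than between-individual variation (`sigma_between`),
which reproduces the qualitative separation reported for real pubic bones
(match RMS well below mismatch RMS, perfect sensitivity and near-perfect
specificity at the sweep-recommended threshold). The template resolution
is a free choice (no reference resolution is published) and was set so the
full 880-superimposition design runs in minutes on one CPU.

What a green synthetic test does **not** establish: performance on real
bones. The generator has no CT noise, no segmentation artefacts, no
fragmentation or taphonomic damage, isotropic smooth deformations rather
than anatomically structured asymmetry, and no size dimorphism between the
two groups. Absolute RMS distributions of real assemblages are therefore
out of reach; the tests check arithmetic anchors, oracle agreement and the
qualitative variance-structure claim only.

## Repeatability protocol

Landmark placement is the only manual step of the protocol, so operator
variation is modelled as Gaussian jitter (default σ = 0.5 mm) on all
landmark coordinates. The protocol re-runs the within-group comparisons
over the first `n_subjects` paired individuals with independently jittered
landmarks per run and reports TEM/rTEM separately over match and mismatch
RMS values (between the first two runs). Zero jitter gives TEM = 0 exactly
— the pipeline itself is deterministic.

## Known limitations

- Rigid-only registration by design; no deformable or scaled variants.
- One-way RMS (moving onto fixed); no symmetric residual.
- ICP is a local optimiser: a grossly wrong landmark initialisation can
  converge to a wrong pose. Non-convergence within the iteration cap is
  flagged (`converged=False`), logged, and retained in the matrix.
- Hollowing assumes the outer shell is visible from outside; deep
  concavities reachable only through narrow openings may be removed at low
  `n_directions`.
- The pooled ("combined") analysis is the union of within-group cells;
  cross-group superimpositions are never computed, matching the reference
  design.
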