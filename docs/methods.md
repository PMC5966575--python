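# Methods

`shapefilt` turns a binary segmentation of a subcortical or ventricular brain
structure into a smooth, topology-correct triangulated surface and a
*filtered* segmentation, by deforming a curated template surface onto the raw
marching-cubes surface of the segmentation. This note documents the models,
the numerical choices, and what the synthetic phantoms do and do not show.

## Pipeline model

Per structure the pipeline runs four stages:

1. **Raw surface extraction.** Marching cubes (Lewiner variant, ambiguous
   cube cases resolved consistently) on the zero-padded binary mask at the
   0.5 iso-level, in world millimetres via the NIfTI affine (voxel-center
   convention, 0-based indices). The raw surface is faithful to the
   segmentation — including its holes, spikes and disconnected fragments.
   `keep_largest_component` (default on for targets) suppresses spurious
   blobs; it is turned off when a genuinely multi-lobed target (e.g. a
   split ventricle) must be presented to the registration whole.

2. **Rigid alignment** of the template vertex set to the raw-surface vertex
   set without correspondences. We alternate a Gaussian soft assignment
   `w_ij ∝ exp(-||s_i - d_j||² / T)` (row-stochastic) with the closed-form
   weighted Procrustes solve (cross-covariance SVD, determinant correction —
   reflections are excluded), while cooling `T` geometrically. The
   per-iteration score `Σ w_ij ||R s_i + t - d_j||²` is non-increasing: the
   Gibbs weights at a lower temperature cannot raise the expected squared
   distance at fixed positions, the Procrustes step minimizes it at fixed
   weights, and a rejection safeguard makes the guarantee unconditional.
   Initialization is centroid matching plus principal axes, with the four
   proper-rotation sign combinations disambiguated by nearest-neighbor
   score. No scaling component is estimated (rotation + translation only).

3. **LDDMM surface matching with a currents data term.** The template
   vertices are flowed by forward Euler (default T = 10 steps) under the
   velocity field `v_t(x) = Σ_j exp(-||x - q_j(t)||²/σ_V²) α_j(t)`, with the
   control points q_j the template vertices themselves. The energy is

        E(α) = γ · (1/T) Σ_t Σ_ij K_V(q_i, q_j) ⟨α_i, α_j⟩  +  ||C(φ(X)) - C(Y)||²_W

   where a surface's current C assigns each face its area-weighted normal
   (half cross product) at its centroid, compared under a Gaussian kernel of
   width σ_W. Currents need no point correspondences and are insensitive to
   triangulation. Gradients are a hand-derived reverse-mode (adjoint) pass
   through the Euler steps and the face-geometry chain rule; the test suite
   checks them against central finite differences (relative error < 1e-7 in
   practice, asserted < 1e-4). Optimization is plain gradient descent on
   zero-initialized momenta with Armijo backtracking; accepted energies are
   strictly non-increasing and iteration stops at a relative change of 1e-6
   or the iteration cap. Because only vertex positions move and the face
   list is reused verbatim, the deformed surface has the template's Euler
   characteristic, component count and connectivity *by construction*; the
   diffeomorphic character of the flow is monitored empirically (no face
   normal flips, all areas positive on converged phantom runs).

4. **Voxelization** of the deformed surface back onto the input grid:
   a voxel is foreground iff its center lies strictly inside the closed
   surface, decided by even-odd parity ray casting along the first voxel
   axis in voxel coordinates (arbitrary affines supported). Rays hitting a
   triangle edge or vertex make a column's crossing count odd; such columns
   are detected and the whole fill is recomputed with a small deterministic
   in-plane ray offset. The published description of this step ("nearest
   neighbor assignment") is ambiguous between inside-labeling and
   nearest-surface-element labeling; strict inside-testing was chosen
   because it is deterministic and makes overlap metrics well defined.

## Template construction and selection

Templates come from curated, noise-free masks. The route: compute the signed
Euclidean distance function of the mask (positive outside, mm), smooth it
with a Gaussian (default σ = 1.5 mm), and *curvature-compensate* by
subtracting `(σ²/2)·Δ(field)` — Gaussian smoothing shifts a level set inward
by approximately σ²/2 times its Laplacian (the mean curvature for a distance
function), and this correction cancels the O(σ²) shrinkage while retaining
the smoothing. The zero level is sampled densely (marching cubes), thinned
to a blue-noise set at ~0.75× the target edge length, tetrahedralized
together with interior anchor points by a 3-D Delaunay triangulation, and
classified inside/outside by the field sign at tet centroids. Non-manifold
(bowtie) edges of the resulting boundary are repaired by greedily toggling
the most ambiguous tetrahedra; the surface is then relaxed tangentially,
re-projected onto the zero level by Newton steps, and its few outlier-long
edges are bisected. The reconstruction retries at 0.85× and 0.7× the edge
length before failing; failure (non-watertight output, or a thin feature
smoothed away into a second component) is an explicit error, matching the
route's intended use on curated masks only. On an ellipsoid phantom the
reconstructed volume is within ~4% of the analytic value and the
edge-length ratio stays under 3.

Template *selection* among candidate meshes of one structure excludes
non-closed candidates, then minimizes the distance of surface area to the
candidate mean, tie-broken by lower total Geometric Laplacian, then list
order.

## Evaluation metrics

- **DSC** `2 V(A∩B) / (V(A)+V(B))`; two empty masks define DSC = 1 with a
  warning. **AVD** `|V(A)-V(B)| / ((V(A)+V(B))/2)` ∈ [0, 2]. **PCC** is the
  Pearson correlation of cohort volume series.
- **Geometric Laplacian.** `GL(v) = v − (Σ l_i⁻¹ v_i)/(Σ l_i⁻¹)` over the
  edge-connected 1-ring with Euclidean edge lengths `l_i`; the surface GL is
  the *unnormalized* sum of vertex-wise norms. It is exactly invariant under
  rigid motion and homogeneous of degree 1 under scaling. Zero-length edges
  are a hard error (clean the mesh first), as silently patching them would
  bias the roughness measure.
- **Outlier QC.** Quantiles by linear interpolation of order statistics.
  Two rules ship: `as_printed` uses bounds [Q1 − 1.5·IQR, Q1 + 1.5·IQR];
  `tukey` uses the standard [Q1 − 1.5·IQR, Q3 + 1.5·IQR]. The `as_printed`
  upper bound (built on Q1) is likely a transcription slip for Q3 in the
  source convention, but both behaviors are provided and `as_printed` is the
  default for fidelity; neither is asserted as the original intent. Note the
  as-printed band is *narrow*: for a normally dispersed sample it sits near
  1.35σ, so ~9% of healthy members of a heterogeneous group will flag. QC
  against it is therefore meaningful for homogeneous, structure-specific
  groups — the tests construct such a group deliberately.
- **Welch's t-test** (unequal variance, two-sided) for group differences;
  the degenerate both-constant-equal-means case returns t = 0, p = 1.
- **CAP score** `age × (CAG − 33.66)` with subgroup boundaries 290 and 368
  inclusive to the mid group.

## Synthetic phantoms

Real cohort MRI data cannot ship with the package, so a seeded generator
produces the three geometry classes the pipeline must handle: ellipsoids
(putamen/pallidus-like), tubes bent along a circular arc
(caudate/hippocampus-like), and two ellipsoidal lobes joined by a thin
bridge (lateral-ventricle-like; bridge radius 1.2 mm ≈ 1–2 voxels on the
default 1 mm grid). Segmentation noise is modeled as boundary-band voxel
flips (default rate 0.05, confined to the one-voxel band each side of the
true boundary), interior holes (3 of radius 1.5 mm), and small disconnected
components (2 of radius 2 mm, placed disjoint with retries). Populations
apply smooth radial perturbations — a degree-1 plus traceless degree-2 form
on the unit direction, i.e. low-order spherical harmonics — plus small rigid
motions (≤10°, ≤2 mm), resampling any draw that loses single-component-ness.
All randomness derives from one integer seed through numpy `SeedSequence`
spawning (member i, attempt a ⇒ `spawn_key=(i, a)`).

What the phantoms do **not** emulate: MRI intensities, bias fields, partial
voluming, anisotropic acquisition, anatomically realistic cortical
neighborhoods, or inter-subject topology differences. Passing tests
demonstrate the geometric and statistical machinery — fidelity, smoothing,
topology rescue, determinism — under controlled noise, not clinical
segmentation accuracy.

## Default parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `iso_level` | 0.5 | mid-level between binary labels |
| `pad_voxels` | 2 | guarantees closed surfaces at volume borders |
| `gaussian_sigma_mm` | 1.5 | template smoothing scale (curvature-compensated) |
| `target_edge_length_mm` | 2.0 | template resolution (~250–450 vertices on subcortical-scale shapes) |
| annealing T₀ | mean squared NN distance | self-scaling start temperature |
| cooling factor | 0.93 | geometric; ~100 outer iterations to T_min |
| T_min | (0.5 mm)² | assignment sharpness at convergence |
| subsample | 2000 points | caps the O(PQ) assignment cost |
| σ_V | 0.3 × template bbox diagonal | deformation stiffness scales with structure size |
| σ_W | 0.5 × σ_V | mismatch sensed at half the deformation scale |
| γ | 0.1 | mild regularization; data term dominates |
| timesteps T | 10 | forward-Euler discretization of the flow |
| optimizer cap | 200 (60 in cohort runs) | backtracking descent iterations |

All are configurable through `PipelineConfig`, which serializes losslessly
to YAML; a run is reproducible bit-for-bit from (inputs, config, seed).

## Problem sizes used in the shipped experiments

The shipped tests and the acceptance script run on 48³–64³ voxel grids at
1 mm spacing, templates of roughly 160–450 vertices, and a 20-member noisy
cohort, chosen so the full suite executes quickly on a single CPU while
every claimed property is still exercised end-to-end. The cohort (20
ellipsoid variants, 10% radial variation, moderate noise) runs the complete
pipeline twice to verify bitwise determinism of the cohort table.

## Known limitations

- The flow is forward Euler with vertex-parameterized momenta; very large
  momenta can in principle break invertibility between steps. The tests
  monitor orientation (no normal flips) rather than proving diffeomorphy.
- The template route is deliberately less robust than marching cubes (it
  errors rather than repairs), and thin features below the smoothing scale
  are reported as topology errors rather than silently reconnected.
- The voxelizer labels by voxel-center containment; structures thinner than
  one voxel after deformation can rasterize disconnected even though the
  surface itself is connected.
- Rigid alignment can lock onto a symmetry-related optimum for shapes with
  near-exact rotational symmetries; the score is then equivalent, but
  vertex-level correspondence is not unique.
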