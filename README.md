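# shapefilt

Deformation-based filtering of subcortical and ventricular shape
segmentations.

Automated segmentations of brain structures (putamen, caudate, hippocampus,
thalamus, amygdala, globus pallidus, lateral ventricles) are voxel masks,
and the surfaces extracted from them by marching cubes inherit every
segmentation error: rough boundaries, interior holes, disconnected
fragments, broken anatomical topology. `shapefilt` filters such
segmentations *in a deformation-based manner*: a curated, smooth,
topologically correct **template surface** is rigidly aligned to the raw
marching-cubes surface and then deformed onto it by **large deformation
diffeomorphic metric mapping (LDDMM) with a currents data term**. Because
the deformation only moves the template's vertices, the output surface keeps
the template's smoothness, connectivity and Euler characteristic while
following the subject's geometry; rasterizing it back to the voxel grid
yields the filtered segmentation. The toolkit is aimed at neuroimaging
pipelines that need per-subject structure surfaces and segmentations that
are simultaneously accurate, smooth, and topologically sound, plus the
evaluation and QC machinery to audit them at cohort scale.

## What is inside

| module | contents |
| --- | --- |
| `shapefilt.volumes` | `LabelVolume` (NIfTI I/O, voxel↔world maps), `TriMesh` (VTK/PLY/OFF I/O), topology summaries |
| `shapefilt.extraction` | marching-cubes extraction, Delaunay-based smooth template reconstruction, quantitative template selection |
| `shapefilt.rigid` | correspondence-free rigid alignment: Gaussian soft assignment + weighted Procrustes with deterministic annealing |
| `shapefilt.lddmm` | currents representation, flow integration, energy/adjoint gradient, surface matching |
| `shapefilt.pipeline` | watertight-mesh voxelization, per-structure filtering, deterministic batch runs |
| `shapefilt.metrics` | DSC, AVD, PCC, Geometric Laplacian, IQR outlier QC, Welch's t-test, CAP score |
| `shapefilt.phantoms` | seeded subcortical-like phantom masks, segmentation-noise model, population sampling |

The core quantities, in the field's notation: the Dice similarity
coefficient DSC(A,B) = 2·V(A∩B)/(V(A)+V(B)); the absolute volume difference
AVD(A,B) = |V(A)−V(B)|/((V(A)+V(B))/2); surface roughness by the Geometric
Laplacian GL(v) = v − (Σᵢ lᵢ⁻¹vᵢ)/(Σᵢ lᵢ⁻¹) summed as Σᵥ‖GL(v)‖₂; and the
LDDMM energy γ·(1/T)Σₜ⟨αₜ, K_V αₜ⟩ + ‖C(φ(X)) − C(Y)‖²_W with Gaussian
kernels K_V (deformation) and K_W (currents mismatch). See
`docs/methods.md` for the full model description and defaults.

## Worked example

Filter a noisy synthetic segmentation of an ellipsoidal structure:

```python
import shapefilt as sf

spec = sf.PhantomSpec(shape="ellipsoid", grid_shape=(48, 48, 48), seed=1)
truth = sf.make_phantom(spec)                         # noise-free ground truth
noisy = sf.corrupt_mask(truth, sf.NoiseSpec(seed=3))  # simulated segmentation

template = sf.delaunay_template_mesh(
    truth, sf.ExtractionConfig(keep_largest_component=False)
)
result = sf.filter_structure(
    noisy, template, sf.PipelineConfig(optimizer=sf.OptimSettings(max_iter=60))
)

m = result.metrics
print(f"DSC(raw mask, filtered mask)   = {m.dsc:.3f}")
print(f"AVD(raw mask, filtered mask)   = {m.avd:.3f}")
print(f"GL(raw marching-cubes surface) = {m.gl_raw:.1f}")
print(f"GL(deformed template surface)  = {m.gl_filtered:.1f}")
print(f"DSC(filtered mask, truth)      = {sf.dsc(result.filtered_mask, truth):.3f}")
print(f"DSC(noisy mask, truth)         = {sf.dsc(noisy, truth):.3f}")
```

Output:

```
DSC(raw mask, filtered mask)   = 0.956
AVD(raw mask, filtered mask)   = 0.002
GL(raw marching-cubes surface) = 392.8
GL(deformed template surface)  = 72.5
DSC(filtered mask, truth)      = 0.997
DSC(noisy mask, truth)         = 0.959
```

Reading the numbers: the filtered segmentation overlaps the input well
(DSC 0.956 — the filter follows the subject's geometry) while its surface is
more than five times smoother (total Geometric Laplacian 392.8 → 72.5), and
it is *closer to the noise-free truth than the noisy input itself*
(0.997 vs 0.959) — the template prior removes noise rather than adding bias.
`result.deformed_surface` reuses the template's face list verbatim, so its
topology is correct by construction.

A command-line interface mirrors the library:

```bash
shapefilt simulate --shape dumbbell_bridge --n 20 --seed 7 --outdir phantoms/
shapefilt extract --in mask.nii.gz --label 1 --method mcubes --out surf.vtk
shapefilt filter --mask mask.nii.gz --label 1 --template tpl.vtk --outdir out/
shapefilt filter-batch --manifest phantoms/manifest.csv --template tpl.vtk --outdir out/
shapefilt qc --surfaces out/ --rule as_printed --out qc.csv
```

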