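# splenvas

Serial-section to 3D-mesh reconstruction of human splenic **red pulp
microvasculature** — terminal arterioles, CD271⁺ sheathed capillaries, the
open capillary network, B-lymphocyte accumulations and venules — as a
tested, reusable Python pipeline, exercised end-to-end on synthetic
stained-section phantoms with known vascular ground truth.

## Who this is for

Labs reconstructing microanatomy from serial brightfield
immunohistochemistry: stacks of RGB sections (0.5 µm/pixel in plane, ~7 µm
thick) triple-stained so that every section carries SMA (brown, smooth
muscle) and CD34 (blue, endothelium) while alternating sections add CD271
(red, stromal capillary-sheath cells) or CD20 (red, B cells). The package
covers the whole chain from raw sections to painted, measurable surface
meshes — and, because no public scanned dataset of this kind exists, it
ships a first-class phantom generator so every stage is testable against
ground truth.

## The method

1. **Normalization & registration** — sections are color-normalized to a
   reference image (Reinhard statistics transfer in lαβ space), the CD34
   channel is color-deconvolved and blurred (σ = 6 px), and sparse blob
   features drive a *stack-global* rigid registration: all per-section
   transforms are refined jointly by Huber-weighted Gauss–Newton, with the
   reference section pinned to the identity. The established transforms are
   applied to the non-blurred sections, followed by a central crop.
2. **Stain unmixing** — Beer–Lambert color deconvolution
   (`OD = −log10((I+1)/256)`, densities = OD·M⁻¹) separates brown/blue/red;
   each stain is re-rendered and converted to 8-bit intensity (blue →
   negated green, brown → negated blue, red → CMYK magenta), stretched over
   the stack-wide range.
3. **Volume building** — dense optical flow between consecutive slices
   interpolates z from 0.5 × 0.5 × 7 µm voxels to 0.5 × 0.5 × 1 µm (SMA,
   CD34) and from 14 µm to 2 µm (CD271); CD20 stays at 14 µm
   (nearest-neighbour resize only). Channel-specific grayscale morphology
   (digital-ellipsoid dilation/closing + Gaussian blur) bridges residual z
   gaps.
4. **Meshing** — marching cubes at iso-value 100 (CD34, CD20) or 160 (SMA,
   CD271); octree watertight repair (depths 9/7/8 at full scale) closes
   surfaces cut by the ROI boundary without relevant shape change
   (symmetric Hausdorff ≤ 2 cells).
5. **Post-processing & painting** — Taubin smoothing (10 iterations), small
   disconnected components removed at 2 % (CD34) / 5 % (CD271) / 10 % (SMA)
   of the mesh's main diagonal, quadric decimation to 10 % (CD34) or 50 %
   (CD271, CD20); CD34 vertices closer than **8.75 µm** to the SMA mesh are
   painted white (arteriolar smooth muscle), the rest blue; B-cell
   components are pruned by size (< 10 µm diameter) and by distance to the
   vasculature.
6. **Recovery scoring** — with phantom ground truth, sheaths, open-ended
   side branches, non-sheathed bypasses and venule contacts are re-detected
   on the meshes by exact point-to-surface distance queries, and sheathed
   paths are measured by on-surface geodesics.

## Worked example

```python
from splenvas import desk_profile, run_pipeline

cfg = desk_profile(seed=1)              # 320 px × 40-section phantom
manifest = run_pipeline(cfg, "out/run1", seed=1)
print(manifest.recovery)
```

prints (abridged):

```
{'sheath_detection_rate': 1.0,
 'side_branch_detection_rate': 1.0,
 'bypass_detected': 3, 'bypass_truth': 3,
 'venule_contacts_detected': 2, 'venule_contacts_truth': 2,
 'long_path_geodesic_um': 325.0, 'long_path_truth_um': 320.0}
```

Every ground-truth capillary sheath and open-ended side branch was
re-identified on the reconstructed meshes, all three non-sheathed bypass
capillaries and both venule contacts were found, and the constructed
four-bifurcation sheathed path (320 µm of centerline) measured 325.0 µm by
on-surface geodesic — a 1.6 % error. Outputs (registered sections, channel
volumes, raw and processed meshes including the painted CD34 surface,
alignment and recovery reports) land under `out/run1/`.

The same pipeline is scriptable from the shell:

```bash
splenvas run --profile desk --seed 1 --outdir out/run1
splenvas roi-volume --sections 83        # -> 0.58 (mm³)
splenvas crop-percent --total 150 --used 84   # -> 44
```

Geometry bookkeeping: 83 sections of 7 µm under a 2000 px crop at
0.5 µm/px represent 0.58 mm³ of tissue; a series of 150 cut sections with
84 usable was cropped by 44 %.

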