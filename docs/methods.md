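# Methods

This note documents the models, parameter choices and numerical conventions
behind `splenvas`, and what the phantom-based validation does and does not
demonstrate about real scanned tissue.

## Imaging model

Brightfield immunohistochemistry is modelled by the Beer–Lambert law. Each
stain *s* has a unit optical-density vector `M[s, :]` over RGB; a pixel
whose optical path crosses stained structures with column density `A_s`
(OD·µm of stain per µm of path, integrated through the 7 µm slab) transmits

    I_c = 256 · 10^(−Σ_s A_s · M[s, c]) − 1 .

Unmixing inverts this per pixel: `OD_c = −log10((I_c + 1)/256)`, densities
`= OD · M⁻¹`, negatives clipped. The `+1/256` offset guards `log 0` for
saturated 8-bit pixels and makes the forward/inverse pair an exact round
trip — on noiseless float renderings the recovered densities agree with the
ground truth to ~1e−15, and the package's acceptance bound of 1e−6 is
comfortably met. The default OD matrix uses the standard published DAB-brown
vector plus representative alkaline-phosphatase blue and red directions
(condition number ≈ 5); phantom rendering and unmixing share one configured
matrix, so phantom-based results exercise the geometry of unmixing, not the
correctness of any particular chromogen calibration. Stain amplitudes
default to 0.12–0.15 OD/µm, which puts a capillary crossing (~6 µm of
stained path) at an OD near 1 — a strongly but not saturatedly stained
structure.

## Phantom

The phantom generates a vessel centerline graph with radii and structure
classes, then renders it into jittered, noisy serial sections.

Geometry defaults (desk scale, 320 × 320 px × 40 sections = 160 × 160 ×
280 µm at 0.5 µm/px and 7 µm sections): terminal arterioles of radius 5 µm
entering nearly perpendicular to the cutting plane, branching into sheathed
capillaries (radius 3 µm) wrapped by CD271⁺ shells (outer radius 8 µm)
covering 1–3 dichotomous bifurcations; short open-ended side branches
(radius 2 µm) crossing the sheath and ending at its surface; an open
network of scattered capillary chains (radius 2.5 µm); three non-sheathed
arteriole-to-network bypasses; a z-spanning venule pair (radius 10 µm) with
two network contacts; five CD20 B-cell spheres (radius 3.5 µm) per sheath.
One sheath is a constructed four-bifurcation helix whose centerline exceeds
300 µm — the elongated-sheath regime reported for human spleen — giving the
geodesic measurement a known truth. Helix rather than zigzag geometry is
deliberate: per-node direction changes of ~40° keep the *surface* geodesic
within a few percent of the centerline length, whereas sharp bends let the
geodesic cut corners by construction, not by reconstruction error.

Per-section acquisition artifacts: rigid jitter (translation magnitude
uniform in 0–10 px, rotation 0–2°, both resampled bilinearly about the
image center), additive Gaussian pixel noise (σ = 3 on the 8-bit scale),
optional lost sections (removed, original indices retained so gaps stay
visible) and defocused sections (Gaussian-blurred, flagged).

**Drift-free anatomy, by design.** Serial-section registration is
fundamentally blind to a smooth anatomical trend across the stack: a net
in-plane tilt of the vasculature is indistinguishable from a progressive
misalignment, and a net twist from a progressive rotation. A registrable
phantom therefore must not carry such trends — which is also the realistic
assumption (isotropic microvasculature has no preferred in-plane drift
direction), enforced here exactly in finite samples: scattered network
chains are instantiated in 4-fold symmetric quadruplets (identity, point
reflection, and both axis reflections through the domain axis), which
cancels both the net drift *and* the net curl of the moving structure
field; arteriole trees are instantiated in point-symmetric pairs. A
majority (85 %) of the scattered chains run within 8° of the z axis; these
long-persistence, low-drift vessels are what carries the registration
information (an oracle-matching experiment shows that without such a
subpopulation, sub-pixel recovery is information-theoretically unavailable
at 7 µm section spacing). Chains may overhang the first/last section — the
tissue continues beyond the block — so end sections keep a realistic
structure density.

What the phantom does **not** emulate: parenchymal texture and
erythrocytes, antigen-retrieval tissue deformation (jitter is rigid),
stain-vector miscalibration, partial-focus blur within a section, and
section-thickness variability. Passing tests therefore demonstrate the
correctness of the pipeline's geometry and numerics under a controlled
optical model — not robustness to every artifact of scanned slides.

## Registration

Features are blob centroids of the σ-6-blurred deconvolved CD34 channel,
subpixel-refined by parabolic fits, and filtered by a Hessian-eigenvalue
roundness gate (λ₂/λ₁ ≥ 0.25): peaks on elongated ridges — vessels running
obliquely through the section — are poorly localized along the ridge and
drift quickly from section to section, so only blob-like maxima survive.
Matching proceeds in stages: NCC patch matching with a ratio test and
RANSAC per pair (each section against its two nearest z-neighbours),
chaining from the reference outward, joint Huber-weighted Gauss–Newton over
all transforms (solved in image-centered coordinates), then transform-guided
re-matching: mutual nearest neighbours in the common frame at shrinking
gating radii (7, 4, 3 px per section of z distance), each partner
re-localized by a local NCC search with parabolic subpixel interpolation.
A final pass adds long-range pairs (up to 6 sections apart, gate
4 px + 1.5 px/Δz, Huber δ = 1.2 px): persistent near-axial vessels anchor
the stack against the rotation random walk that nearest-neighbour chains
accumulate. The final gate is deliberately generous — a tight gate would
discard exactly the peripheral matches that constrain rotation and freeze
any residual twist in place.

On default phantoms the recovered transforms reproduce the ground-truth
jitter with 0.2–0.6 px RMS over structure pixels across seeds (≤ 0.5 px on
the reference seed). The transform family is rigid (rotation +
translation); serial paraffin sections justify this default and the
contract is stated in terms of match residuals, not detector identity.

## Volumes

Optical-flow interpolation uses iterative Lucas–Kanade flow
(coarse-to-fine, radius 12, 3 warps) in both directions between each slice
pair; the intermediate slice at fraction α blends the two forward warps.
Original slices are copied through bit-exactly; output slice count is
`(Z−1)·factor + 1` (endpoints preserved), z-spacing divided by the factor,
and the volume origin shifted by `(s_old − s_new)/2` so original slice
centers stay at their world positions (voxel-center convention:
`world = origin + (index + ½)·spacing`; section *k* spans
`[k·7, (k+1)·7] µm`, its slice center at `k·7 + 3.5`). At full scale, 83
sections → 575 slices ≈ 575 µm of depth; the ~6 µm discrepancy with naive
83 × 7 is the endpoint convention, not data loss.

Grayscale dilation/closing uses digital-ellipsoid structuring elements
(voxel centers inside the ellipse of the stated x-y-z radii), implemented
by exact decomposition of the ellipsoid into its maximal symmetric boxes —
each box a separable running max/min — because a direct footprint filter is
O(|SE|) per voxel and infeasible on interpolated volumes. Border handling
is edge replication. Equality with brute-force morphology is asserted in
tests. Filtering happens on interpolated volumes; CD20 passes through
untouched and keeps its native 14 µm spacing (anisotropy is carried by the
mesh spacing metadata; `nn_resize_z` is available when an isotropic grid is
wanted).

## Meshing and repair

Marching cubes uses linear edge interpolation with the tie rule "value
exactly equal to the iso-value counts as inside" (implemented as an
infinitesimal level offset); vertex coordinates are world µm via spacing
and origin, faces wound for outward normals. One documented artifact:
marching cubes on *binary* (0/255) data inflates surface area by ~10 % on
spheres (fixed-fraction edge crossings make the facet field jagged) while
enclosed volume stays within ~1.5 %; on band-limited data — a one-voxel
partial-volume edge profile, or the blurred volumes the pipeline actually
meshes — area is accurate to well under 5 %. Both behaviors are pinned in
tests. Large vessels reconstructed per-color produce double-walled
envelopes (outer + inner surface); this is expected behavior of surface
reconstruction, reproduced rather than suppressed.

Watertight repair rasterizes the surface into a `2^depth` grid over the
padded bounding cube (dense barycentric sampling at half-cell spacing),
dilates one cell to seal the crust, flood-fills the exterior from the
border, erodes the dilation back off, and re-extracts the solid boundary
with marching cubes. The output is a closed 2-manifold; for already-closed
inputs the symmetric Hausdorff distance to the input is ~1 cell (bound: 2
cells). The desk profile uses octree depths one level below the full-scale
reference values (8/7/7/7 vs 9/7/8/8) because the desk volume's bounding
cube is less than half the full-scale one — the absolute cell size stays at
or below the full-scale equivalent.

## Mesh operations

* Taubin smoothing: uniform-weight Laplacian, λ = 0.5, µ = −0.53, 10
  iterations; volume change is an order of magnitude below plain Laplacian
  smoothing at equal iterations.
* Small-component removal: a component is dropped when its bounding-box
  diagonal is below the stated fraction of the whole mesh's main diagonal.
* Quadric decimation: classic QEM edge collapse with a lazy heap; a
  collapse requires the link condition (the two vertex neighbourhoods share
  exactly two vertices), preserving manifoldness; the new vertex minimizes
  the combined quadric with midpoint/endpoint fallback.
* Proximity painting: per-vertex exact point-to-triangle distance (KD-tree
  candidate prefilter with a provably conservative radius, so results equal
  brute force); strict `<` comparison at the 8.75 µm threshold.
* B-cell pruning: components below 10 µm bounding-sphere diameter, or
  farther than a configurable distance (default 25 µm — the sheath outer
  radius plus a generous B-cell excursion; no reference value exists) from
  every reference mesh, are removed. "Diameter" is a near-minimal bounding
  sphere (Ritter with refinement), appropriate for spheroid cells.
* Geodesics: Dijkstra on the vertex + edge-midpoint graph (midpoints
  connected within each triangle), which brings the graph-metric
  overestimate to ~0.5 % on smooth tubes. For the sheathed-path
  measurement the central capillary is first isolated — vertices within
  the sheath's outer radius + tolerance of the ground-truth centerline, the
  component reaching both endpoints — the ground-truth-driven analog of
  isolating a vessel by mesh painting before measuring it; the isolated
  patch is subdivided twice and lightly smoothed before the graph search,
  since decimated tubes are too coarse for an accurate graph metric.

## Recovery scoring

Ground truth is mapped into the reconstruction frame by the reference
section's true jitter plus the crop offset (the registered stack lives in
the reference section's raw pixel frame). Detection rules, at a default
tolerance of 5 µm: a sheath is detected when the median distance of
mid-shell sample points to the CD271 mesh is at most half the shell
thickness plus tolerance; an open-ended side branch when its free end lies
within its radius plus tolerance of the CD34 surface; a bypass or venule
contact when all centerline samples lie within the vessel radius plus
tolerance of the CD34 surface.

## Pipeline

One global seed fans out to per-stage seeds by SHA-256 derivation (all
below 2³¹), so stages are independently reproducible. Each stage writes its
outputs with checksums into a manifest; a re-run with the same
configuration hash and seed reloads a verified completed run from disk
(run-level caching). Stage failures abort with the stage named; partial
outputs are preserved. Configuration is a YAML file with per-channel
blocks; `fullscale_profile()` carries the full-scale reference
parameters (iso 100/160, depths 9/7/8, fractions 2/10/5 %, decimation
10/50 %, 2000 px crop), `desk_profile()` the test-scale variant. The
full-scale profile is supported but not exercised by the test suite; tests
and the acceptance script run at desk scale, where the complete pipeline
takes a few minutes on one CPU.

## Known limitations

* Sparse feature registration needs a persistent low-drift structure
  population; stacks consisting solely of steeply oblique vessels cannot be
  registered to sub-pixel accuracy by any method at 7 µm spacing.
* Quadric decimation is implemented in Python; at full scale (meshes of
  tens of millions of faces) it is the dominant cost.
* The optical model omits scattering, chromogen saturation and scanner
  color profiles; stain vectors are configured, never fitted from data.
* `recover_topology` presumes phantom ground truth; it is a validation
  surface, not an automatic annotation tool for real tissue.
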