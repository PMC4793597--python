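# Methods

This note documents the models, conventions and numerical choices behind
`ctoam`, and what the synthetic validation does and does not establish.

## Coordinate conventions

Volumes are 0-based voxel-index arrays `[i, j, k]`; physical positions are
`origin + index · spacing` (mm). The three axes carry anatomical labels:
axis 0 proximodistal (index 0 at the proximal top), axis 1 dorsoplantar
(along the trochlear ridges, index 0 at the end face the tilted view looks
into), axis 2 mediolateral. All operations that need anatomy (view
construction, mirroring) go through these labels; everything else is
label-agnostic.

## Segmentation

The reference workflow used a commercial tool whose segmentation operator
is not published, so the package uses the minimal reproducible stand-in:
global threshold (default 250 HU — above soft tissue, below trabecular
bone), 26-connected component labelling, suppression of components below
`min_component_voxels` (default 27 = a 3³ cube), keep-largest policy, and a
one-voxel 6-connected binary closing to seal pinholes in the shell. Surface
extraction (mask voxels with a 6-connected background neighbour) is
reported for completeness; the projection stage finds the articular surface
by ray order instead and treats a hollow shell's inner faces like any other
bone/background interface.

## Projection model

Views are orthographic: parallel rays along the line of sight, an
orthonormal in-plane basis (u = image columns, v = image rows), and a pixel
grid that tightly bounds the projected mask silhouette plus a one-pixel
margin, so image extents are deterministic. The proximal view looks along
the proximodistal axis; the distal view is that frame rotated by
`tilt_deg` (default 90°) about the mediolateral axis, which keeps u — and
hence left/right mirroring — identical across views.

The subchondral plate is realised as a depth window rather than a separate
3-D plate mask: each ray is sampled at a uniform step (default min
spacing/4; an error if coarser than min spacing/2), the first sample whose
nearest voxel is masked fixes `t0`, and the pixel value is the maximum HU
over `t ∈ [t0, t0 + depth]` (default depth 1.5 mm, the nominal plate
thickness) restricted to masked samples. For MIP purposes this is
equivalent to isolating the plate first, and it removes one under-specified
step. HU interpolation is trilinear by default; in `nearest` mode both mask
and HU use deterministic half-up rounding to voxel centres, which makes the
caster exactly reproducible by an independent per-voxel-column oracle
(`brute_force_mip`) on axis-aligned views — the basis of the exact
equivalence test. Window membership uses a 1e-9 mm tolerance so equal-depth
boundaries cannot flicker.

## Quantisation and maxima

The false-colour scale and the 8-bit conversion share one fixed window,
200–1200 HU. The window endpoints of the 8-bit conversion are not dictated
by the source workflow; fixing them to the display window keeps the eight
bins absolute across subjects (a per-image min/max mode is available behind
`per_image=True`). Quantisation is
`eight_bit = floor(255 · clamp((HU − 200)/1000, 0, 1))`, bins are
`eight_bit // 32`; all interval rules are half-open with the top value
clamped into the highest band/bin, so the mappings are total and monotone.

Density maxima are 8-connected regions of top-two-bin pixels; regions under
`min_area` (default 5 px, a choice made here to suppress single-pixel
noise — configurable) are dropped. The largest survivor is flagged primary,
ties broken by smaller centroid row then column. Note the primary flag is
not stable under mirroring when two regions tie exactly in area (as happens
with deliberately symmetric phantoms); analyses that must be mirror-stable
should pool all maxima, which is also the default for MAR. MAR pools every
retained region because a joint frequently carries a focal secondary
maximum besides the main one; `primary_only=True` restricts it.

The 30 × 30 grid spans the bounding box of the surface footprint, cell
`= floor(30 · (coord − min)/extent) + 1` clamped to 30 at the far edge; a
maximum's cell is that of its area centroid. Right-limb coordinates mirror
as `x → 31 − x`.

## Statistics

Side comparisons use the equal-variance two-sample Student's t-test (the
named test's classical form); subject comparisons one-way ANOVA with
Bonferroni-adjusted all-pairs t-tests once the omnibus test is significant
at α = 0.05. Grid coordinates are analysed per axis (x and y separately);
how to treat the two axes jointly is genuinely open, and per-axis is the
simplest defensible choice. Limbs are treated as unpaired, matching the
unpaired form of the named tests; pairing within subject is a possible
refinement, not implemented. Two degenerate cases are made explicit rather
than numeric: both groups constant and equal reports "no difference, test
undefined", and subjects with a single observation are excluded with a
warning. Summaries use the sample (n−1) SD.

## The phantom and its ground truth

The phantom is a stated world, not a tuning knob: two parallel half-cylinder
ridges (radius 6 mm, centre separation 14 mm, length 30 mm) on a base block
(height 8 mm), voxel size 0.5 mm isotropic in a 48 × 72 × 64 volume;
soft tissue 50 HU, trabecular bone 400 HU, subchondral shell 700 HU within
1.5 mm of the outer surface (Euclidean distance transform), and one
1150 HU patch per ridge — the radial annulus `[r − shell, r]` intersected
with a 4 mm-geodesic-radius disc about a centre given by axial fraction and
circumferential angle. Membership is decided at voxel centres; Gaussian
noise (default cases: 0 and 30 HU) is added last and not truncated. The
voxelised solid is regularised by the same idempotent one-voxel closing the
segmenter applies, so the constructed bone has no sub-voxel crevice at the
ridge–block junction and noiseless segmentation recovers it exactly.

Because the ridges are straight, the 90°-tilted view sees them end-on: only
surface within the MIP depth of the end face is visible there. The default
patches therefore sit near that face (axial fraction 0.03, angles ±25°
toward the medial/lateral borders), which is what lets both views detect
both patches. This is a geometric limitation of the phantom, not of the
pipeline; a real trochlear ridge curves, so the tilted view covers its
distal surface naturally.

Ground truth is computed from the continuous geometry, never from voxels:
each canonical view's silhouette and per-patch visibility maps come from
ray-marching closed-form membership tests at a 0.05 mm step on the same
pixel pitch the pipeline uses, giving the true projected patch fraction
(what MAR should recover) and the true grid cell of each patch. Truth and
pipeline discretise independently, so recovery tests use ±1 grid cell and
±3 MAR percentage points.

### What a green phantom test does not establish

The phantom has uniform tissue classes, sharp boundaries, isotropic voxels
and purely additive Gaussian noise. It does not model beam hardening,
partial-volume blur, cartilage, anatomical shape variation, or touching
tarsal bones — so passing recovery tests establishes the correctness of the
computational chain, not segmentation robustness on clinical scans.

## Known limitations

- DICOM series input requires `pydicom` (not a dependency); NIfTI is the
  supported interchange format, and the rescale arithmetic is exposed as
  `rescale_to_hu` for callers assembling volumes themselves.
- Orthographic projection only; surface-normal ("curvature-following")
  projection is out of scope, and the small visual overlap between the two
  views on a curved surface is accepted, not corrected.
- The between-view transitional band means a patch near the silhouette edge
  of one view is foreshortened there; the grid tolerance absorbs this for
  the default phantom but steeply inclined patches will bias MAR low.
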