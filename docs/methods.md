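# Methods

This note records the models, conventions and numerical choices behind
`fracture3d`, and what the synthetic phantom does and does not show about
real data.

## Coordinate and box conventions

Voxel arrays are indexed `(row, col, slice)`, 0-based; row is image Y
(top→down), col is image X (left→right). Physical coordinates are a plain
scanner-grid frame: x = col × pixel-spacing-x, y = row × pixel-spacing-y,
z = slice × slice-thickness, origin at the corner of voxel (0, 0, 0).
`ImageOrientationPatient` is deliberately ignored (logged if present and
non-axial): the pipeline only needs in-plane spacing and slice thickness
to translate pixels into distances, and mesh and mask live in the same
frame by construction.

Boxes are half-open in pixel index space: a box (x, y, w, h) covers
columns [x, x+w) and rows [y, y+h), so its area is exactly w·h pixels and
adjacent boxes tile without overlap. The z-slab of slice k is likewise
half-open, [k·t, (k+1)·t). File formats are 0-based and say so in their
header line. The flip formula `x' = W − x − w` and the exact
area/IoU arithmetic both follow from this convention.

## DICOM I/O

Only the header fields the pipeline consumes are modelled: Rows/Columns,
PixelSpacing (note DICOM stores it (row, col) = (dy, dx)), SliceThickness,
the rescale pair, and a slice-position sort key (ImagePositionPatient z,
falling back to SliceLocation, then InstanceNumber — the sort key is not
standardized across writers, so the fallback chain is explicit). Missing
rescale tags default to slope 1 / intercept 0 with a warning rather than
an error, because synthetic and anonymized series frequently omit them.
On write, HU are stored as unsigned 16-bit with intercept −1024, making
the write→read round trip exact for integer HU (real CT is integral).
PNG windowing uses round-half-away-from-zero so the window midpoint maps
deterministically to 128; the window itself is a config value
(default −200 to 1800 HU, spanning soft tissue to cortical bone) because
no single clinical window is canonical for detector input.

## Bone segmentation and surface reconstruction

Bone is segmented as the closed HU interval [1150, 1250] — the cortical
band; both bounds are configurable because the upper bound may exclude
denser cortical bone on real scanners. Thresholding is monotone by
construction: widening the band never removes voxels.

The surface is a marching-cubes isosurface at level 0.5 of the binary
mask, with vertices scaled to millimetres. The mask is zero-padded one
layer in-plane only, so structures touching the lateral borders close,
while bone reaching the first/last slice stays open there. Capping then
closes exactly those openings: each boundary loop lying in a constant-z
plane is extruded half a slice outward and closed with a triangle fan to
its centroid, oriented consistently with the adjacent faces. The
half-slice extrusion matters quantitatively: the isosurface passes
through voxel centers, so without it a structure spanning n slices loses
t/2 of material at each end (a 10-voxel cube would measure 900 mm³
instead of ~1000). With it, enclosed mesh volume agrees with voxel count
× voxel volume to within a few percent for compact structures; the test
suite asserts 5% for a 10³ cube and 10% for the hollow-shell phantom.
Boundary loops that are not planar in z are reported as an error, never
silently capped. Connected components under 20 voxels (configurable) are
dropped as thresholding specks before meshing. Mesh smoothing is
deliberately not applied: over-smoothing can visually erase exactly the
fracture lines the pipeline exists to show.

## Phantom

The phantom is a hollow tube: cortical shell at 1200 HU (band center)
between an inner and outer radius, soft tissue at −50 HU inside a
surrounding cylinder, air at −1000 HU beyond. Defaults are a 512×512
in-plane grid (matching the detector's default input size), 0.8 mm
pixels, 1 mm slices, radii 60/42 px. Fractures are either angular gaps
in the shell (background HU replaces a wedge of the ring over a slice
range) or in-plane displacements of the whole cross-section. The seeded
cohort generator draws gaps of 40–80° spanning 4–8 slices at uniform
angular positions — a plain stand-in for the variability of cortical
disruptions across a fracture cohort.

Ground truth needs a reproducible definition (clinical boxes are drawn
by hand): the box on a slice is the tight bounding box of the symmetric
difference between the fractured and unfractured shell masks. Noise is
Gaussian in HU, truncated at ±3σ, so that with σ ≤ 15 the shell provably
stays inside the cortical band and noiseless-band tests remain exact;
the generator's default is σ = 0 so thresholding oracles are bit-exact.
All randomness flows from a single seed; identical specs give
bit-identical volumes.

What the phantom does not emulate: trabecular texture, partial-volume
blur at the cortical boundary, beam hardening and metal artifacts,
anatomically shaped bones, or multiple bones per slice. Passing tests
therefore demonstrate the geometric and statistical machinery —
segmentation, lifting, stacking, matching, PR/AP arithmetic — not
clinical detection performance.

## Rule-based gap detector

Per slice, the detector thresholds into the cortical band, takes the
foreground centroid, and bins shell pixels by polar angle (bin count
adaptive, ≈ one bin per 2 px of circumference, clamped to [36, 720]).
Maximal circular runs of empty bins are candidate gaps; a run whose arc
length at the mean shell radius reaches `min_gap_px` (default 5 px)
becomes one detection. The reported box is the bounding box of the
missing arc reconstructed between the 2nd and 98th percentile of the
shell radii (robust inner/outer radius estimates), and the score is the
gap arc over half the circumference, clipped to [0, 1] — larger gaps
score higher. The detector assumes one ring per slice; it is exactly
invariant to HU perturbations that never cross the band, and completely
deterministic. On the seeded phantom cohort it recovers every fractured
slice with IoU ≈ 0.6–0.7 against ground truth.

## Network scaffold

The one-stage detector follows the CSPDarknet-53 / SPP / PAN layout. The
backbone is a 3→32 stem plus five CSP blocks with (1, 2, 8, 8, 4)
residual units and output channels (128, 128, 256, 512, 1024), each
block halving the spatial size, so a 512×512×3 input yields
256×256×128 … 16×16×1024. Every convolution is followed by batch
normalization and mish. Each CSP block downsamples with a stride-2
convolution, splits the channels into an identity path and a residual
path, and merges with a 1×1 transition. The neck applies SPP (stride-1
max pools of 5/9/13 concatenated with the input) to the deepest map,
then a PAN: top-down upsampling merges into the stride-16 and stride-8
maps, and a bottom-up pass returns localization detail. Three heads emit
3 anchors × (4 box offsets + objectness + class score) per cell at
strides 8/16/32.

The network is implemented on a small reverse-mode autodiff engine over
NumPy (conv2d via per-tap matmuls, full batch-norm backward, fused
stable BCE-with-logits), verified against finite differences in the test
suite. Choices the architecture description leaves open and how they
were fixed: input size 512 (inferred from the first block's 256×256
output; any multiple of 32 is accepted and all maps scale
proportionally); anchors default to the standard 9-anchor layout; NMS
IoU threshold 0.5; the loss is a standard one-stage composition
(λ=5 coordinate MSE on sigmoid-offsets and log-scales, BCE objectness
with λ=0.5 on negatives, BCE class), since no specific composition is
canonical. Training honours the published schedule — Adam, initial lr
0.001 halved every 20 epochs, at most 50 epochs, minibatch 4 — and the
desk-scale contract is that the loss falls on a small phantom set, which
the tests exercise at a 32×32 input (a few minutes of CPU); nothing at
desk scale approximates a clinically trained detector, which is why the
rule detector is the default end-to-end engine.

## Evaluation

Matching is the conventional greedy detection protocol: predictions in
descending score order (deterministic geometric tie-break) each claim
the unmatched same-slice ground-truth box of highest IoU, provided IoU ≥
0.5. The PR curve sweeps the threshold over all distinct scores; because
greedy assignments of higher-scored predictions never change as the
threshold drops, the sweep is computed cumulatively and provably equals
per-threshold re-matching (the tests verify this against a brute-force
re-matcher to 1e-9). AP defaults to all-points interpolation (area under
the monotone precision envelope), with the 11-point variant available
since published AP values do not always state their definition.
Degenerate conventions, each logged: precision with no predictions is
1.0, recall with no ground truth is 1.0, and the sample SD of a single
matched IoU is reported as 0 with a warning. IoU statistics are over
matched pairs only by default. TN is tracked but enters no metric — it
is undefined for box detection.

## Mask stacking and overlay

Lifted cuboids are grouped with a union-find: two cuboids join one
component when their in-plane footprints overlap with positive area and
at most `merge_gap` empty slices separate them. The default merge_gap of
1 tolerates a single-slice detector miss without splitting a fracture in
two; merge_gap 0 still fuses slabs that actually touch. Voxelization
back onto the source grid is exact for grid-aligned cuboids (volume =
Σ area × thickness for disjoint boxes). The overlay scene (bone mesh in
bone color, cuboids in semi-transparent red) exports as glTF with a
matplotlib-rendered PNG snapshot at a fixed camera, keeping outputs
deterministic; mesh and mask must carry the same series id or the
overlay refuses to combine them.

## Pipeline scale choices

The bundled pipeline defaults generate ten 512×512×40 phantom cases
(about 40 MB of DICOM per case); the test suite runs the same stages on
96–128 px grids, which preserve every geometric property at a fraction
of the cost. The end-to-end acceptance checks use the full-size
ten-case cohort, which completes in well under a minute.

## Known limitations

Single-ring assumption in the rule detector (one bone per slice);
displacement fractures are generated but the gap detector is designed
for gaps; no multi-frame DICOM, compressed transfer syntaxes, or
non-axial acquisitions; the network scaffold targets correctness and
trainability, not throughput, and ships no pretrained weights; fragments
are not segmented individually — the pipeline marks fracture regions,
not fragment boundaries.
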