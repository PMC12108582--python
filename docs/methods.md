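# Methods

## Problem and pipeline

Post-ACLR bone tunnels appear in HR-pQCT knee slices as low-density,
roughly circular regions cut through bright trabecular bone. The pipeline
segments the tunnel cross-section on every slice, stacks the 2D masks into
a 3D region of interest (no inter-slice smoothing — the acquisition is
analyzed exactly as annotated), and computes trabecular indices inside it.
All coordinates are `(slice, row, col)`, 0-based; voxel spacing is one
isotropic scalar in mm carried as metadata (default 0.0607 mm, the
XtremeCT-II voxel size) and never inferred from files. Intensities are kept
as stored; no Hounsfield/BMD calibration is applied, and the 8-bit-like
0–255 scale of the fixtures is an assumption, not an assertion.

## Segmentation network

The model is a fully-convolutional residual encoder / U-net decoder.
Encoder: 7×7 stride-2 convolution (width `b`, 64 in the full model) and
3×3 stride-2 max pooling, then four bottleneck stages (1×1 → 3×3 → 1×1
with projection shortcuts) of widths `4b, 8b, 16b, 32b`, repeated
3, 4, 6, 3 times, with stride-2 reduction in the last three stages. Every
convolution is followed by batch normalization and ReLU. All stride-2
operators use "ceil" arithmetic, so any H×W ≥ 32 input reaches a
⌈H/32⌉×⌈W/32⌉ bottleneck — 19×19×2048 for 600×600 — and the decoder
(nearest-neighbour upsampling to each skip's exact size, concatenation,
two 3×3 conv-BN-ReLU blocks, widths `4b…b/4`, final 1×1 to 2 classes)
returns the input size. Inference binarizes by per-pixel argmax,
equivalent to a 0.5 probability threshold for two classes.

The implementation is NumPy with explicit backward passes; convolution is
evaluated as k² shifted 1×1 products (one BLAS matmul per kernel offset),
which bounds peak memory at large slice sizes. Gradients were verified by
finite differences layer-by-layer and on composed blocks. Pretrained
encoder weights are supported only as a local weights file
(`TrainConfig.pretrained_encoder`); nothing is downloaded.

Training defaults follow the clinical study recipe: dice loss on the
softmax foreground probability, Adam with β₁ = 0.9, β₂ = 0.999, weight
decay 10⁻¹⁰ (L2 added to the gradient), learning rate 10⁻⁴, 100 epochs,
batch 12. The "gradually decreasing" schedule is concretized as step decay
×0.5 every 25 epochs; both knobs are configurable. No data augmentation is
applied by default. Train/validation splitting is stratified by
compartment with largest-remainder allocation, so the global train count
is `round(f·n)` while every stratum's proportion matches the whole within
one item (493 femora + 565 tibiae at f = 793/1058 split exactly 793/265).

The desk-scale overfit demonstration (tests, examples, acceptance script)
uses the reduced-width variant (`ModelSpec.small()`: width 8, one block
per stage — identical stride arithmetic) with a constant 2×10⁻² learning
rate over a 200-step budget, chosen for robust convergence of this tiny
model across seeds; the full-scale defaults above are untouched.

## Morphometry

Local thickness follows the maximal-inscribed-sphere definition: the
thickness at x is the diameter of the largest sphere containing x that
fits in the structure. Sphere radii come from the Euclidean distance
transform with a surface convention (EDT − ½ voxel), so an n-voxel slab
measures n voxels for odd n and n − 1 for even n — a known ±1-voxel
discretization property of voxel-centred spheres. Spheres are painted in
decreasing-radius order via one complement-EDT pass per distinct radius;
this is algebraically identical to the exhaustive search (the test suite
checks voxel-for-voxel agreement with a brute-force oracle on small
grids).

Within a tunnel ROI:

* the bone/background threshold is Otsu's method on ROI-interior
  intensities (deterministic, parameter-free; a fixed value can be
  supplied); bone is strictly above the Otsu cut, or ≥ a fixed cut;
* phases are binarized over the **whole** grid with that threshold, and
  thickness maps are averaged over phase voxels inside the ROI — this
  avoids truncating spheres at the ROI wall, which otherwise biases Tb.Sp
  low by more than a voxel for gaps wider than ~½ the ROI radius;
* **BV/TV** is the exact voxel-count ratio |bone ∩ ROI| / |ROI|;
* **Tb.Th / Tb.Sp** are volume-weighted means of the local thickness of
  the bone / non-bone phase (mm);
* **Tb.N** (default "direct") is the reciprocal of the mean spacing
  between bone mid-axes. The mid-axis is the local-maxima ridge of the
  bone EDT (a topological skeleton thins plates to curves and lets spheres
  leak through; the ridge keeps sheets). The spacing is the mean local
  thickness of the ridge complement inside the ROI plus one voxel for the
  ridge sheet itself; for a plate lattice of period p this yields 1/p. The
  plate-model formula (BV/TV)/Tb.Th is available as a config alternative —
  which formula the reference clinical toolchain uses is not documented;
* **volume** is exactly count × spacing³ (mm³); **mGV** is the unweighted
  mean of per-slice mean intensities inside the mask (empty slices are
  skipped; a voxel-weighted variant exists).

Degenerate inputs: an empty tunnel mask is an error; a tunnel that is
entirely bone gives BV/TV 1 and Tb.Sp 0; a uniform-intensity interior has
no separable phases and counts entirely as bone.

## Segmentation metrics and agreement

Precision, recall, IoU, pixel accuracy and dice come from the pixel
confusion counts, with identity-consistent 0/0 conventions (two empty
masks score 1; an empty prediction against a nonempty truth scores 0).
Pairwise agreement between mask sources (model detections "DR" and
annotators "D1…") is macro-averaged per slice by default — matching the
"mean IoU / mean PA" reading — with pixel-pooled micro-averaging as an
option; within a pair the first-named source plays the prediction role,
which is what makes the P and R rows asymmetric.

## Phantoms

The generator emulates what the pipeline needs from real scans: a bright
quasi-periodic trabecular phase, a dark background, a slice-aligned
cylindrical tunnel of known axis/radius, partial bone refill (a seeded
uniform fraction of carved voxels restored to bone intensity), Gaussian
intensity noise, and per-slice ground-truth masks. Plates (not rods) are
the default lattice because every index has a closed form. It does **not**
model anatomical curvature, oblique tunnels, scanner physics (beam
hardening, ring artifacts), or biological remodeling; passing tests
demonstrate correctness of the measurement chain on known geometry, not
segmentation accuracy on clinical images — the published validation scores
of the original study require its private dataset and are out of scope.

## Cohort summaries

Per-compartment n, mean, SD, min, max per metric, plus pooled ranges.
Sample (n−1) SD is the default (population SD is a switch; the convention
behind the printed clinical SDs is not stated, so SDs are reported but not
treated as reference values). Statistics are kept at full precision;
rendering rounds half-away-from-zero at the printed precisions (3 decimals
for fractions/mm, 2 for mm⁻¹, integers for mm³). A single-row group
renders a blank SD rather than 0.

## Problem sizes

The test suite and acceptance script use: 16³-voxel structures for the
brute-force thickness oracle (it is O(n²) in structure voxels),
50×60×60-voxel plate phantoms at spacing p/10 for parameter recovery,
8 slices of 64×64 for the overfit run (200 steps), and the full-width
network once at 600×600 for the shape contract. These sizes were chosen so
the whole suite completes in about a minute on a single CPU while every
tolerance stays at its stated value.

## Known limitations

* Even-width structures under-measure thickness by one voxel (sphere
  centres are voxel centres); sub-voxel accuracy would need upsampling or
  anchored sphere centres.
* The ridge-based Tb.N is exact on plate lattices but only approximate on
  irregular structures; no claim is made that it matches the reference
  clinical toolchain's (undocumented) formula.
* Batch normalization statistics make training loss histories reproducible
  only per platform/BLAS; seeds fix everything else.
* NIfTI inputs are read in native array order and assumed isotropic; the
  affine is not interpreted.
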