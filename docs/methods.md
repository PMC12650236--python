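# Methods

`cacseg` implements an anatomically guided pipeline for segmenting and
quantifying coronary artery calcification (CAC) in cardiac CT. This note
documents the models and procedures it implements, the parameters that
matter, what the synthetic phantoms do and do not emulate, and the design
choices made where the method leaves details open.

## Pipeline overview

1. **Standardization** — stored pixel values are converted to Hounsfield
   units (HU) via the DICOM rescale slope/intercept, clipped to a broad CT
   window, resampled to an isotropic grid (linear for images,
   nearest-neighbour for label masks), and normalized per scan.
2. **Anatomical cascade** — a heart-stage model yields a 3D heart region
   of interest (ROI); a vessel-stage model, fed vesselness-enhanced
   inputs, segments the coronary tree inside the ROI; dilating the tree
   gives a *vessel prior* restricting where lesions may plausibly occur.
3. **Calcification ensemble** — four 2D encoder–decoder variants (U-Net,
   Residual U-Net, Attention U-Net, UNet++) predict per-slice lesion
   probabilities inside the ROI; their maps are fused by *rank-based
   selective ensembling* under the vessel prior; slice masks are
   re-stacked and mapped back to the original grid.
4. **Quantification** — per-slice lesions ≥130 HU and ≥1 mm² are
   extracted and Agatston-scored (area × density weight from peak HU).

## Preprocessing

* Window default `(-1024, 3071)` HU: spans air to dense calcium without
  clipping any ≥130 HU content. Exact bounds are a package default, not a
  prescribed value; both bounds and the min–max vs z-score choice are
  configurable (`preprocess:` YAML block).
* Isotropic target spacing 1.0 mm. Output shape is
  `round(shape·spacing/target)` per axis; nearest-neighbour label
  resampling can only reproduce input labels, never invent new ones.
* z-score uses the population standard deviation (ddof = 0). A constant
  volume min–max-normalizes to all zeros (empty phantom ROIs occur in
  tests); z-scoring a constant volume is an error.

## Vesselness

The multiscale Hessian line filter (the classic Frangi measure) with
scale-normalized (γ = 2) Gaussian derivatives:

    R_A = |λ2|/|λ3|,  R_B = |λ1|/√(|λ2 λ3|),  S = √(λ1²+λ2²+λ3²)
    V = (1 − e^{−R_A²/2α²}) · e^{−R_B²/2β²} · (1 − e^{−S²/2c²})

zeroed where λ2 > 0 or λ3 > 0 for bright-on-dark structures; the
response is the maximum over scales. Defaults: scales {1.0, 1.5, 2.0,
2.5} mm (bracketing coronary calibres on a 1 mm grid), α = β = 0.5, and
`c` auto-set to half the per-scan maximum Hessian Frobenius norm.
Vesselness is computed in 3D on the ROI volume even though the
segmentation models are 2D, because tubularity is inherently
three-dimensional. The volume mean is subtracted before differentiation
so truncated derivative kernels return an exact zero on constant input.
Whether vesselness joins the intensity as a second channel (`stack`,
default) or replaces it partially (`blend`) is configurable.

## Network variants

All variants share one skeleton: `depth` 2×2 max-pool down-samplings
(depth+1 resolution scales), channels doubling from `base_channels`
(64→1024 at the reference configuration), two biased 3×3 convolutions +
ReLU per block with **no normalization layers**, 2×2 stride-2
transpose-convolution upsampling with biases, and a biased 1×1 output
head. At the reference configuration this puts the plain U-Net at exactly
31,030,593 trainable scalars (31.03 M).

Where the variant-specific inner dimensions are open, the package pins:

* **Residual U-Net** — residual double-conv blocks, 1×1 projection
  shortcut whenever the channel count changes, ReLU after the addition
  (32.43 M at reference).
* **Attention U-Net** — additive attention gates on each skip; gating
  signal is the upsampled decoder feature; inner channels = skip
  channels / 4, biased 1×1 convolutions throughout (31.21 M).
* **UNet++** — nested dense skip pathways `X[i][j]` with
  transpose-conv upsampling `C[i+1]→C[i]` and double-conv fusion of
  `(j+1)·C[i]` channels; one 1×1 deep-supervision head per dense column,
  averaged (after sigmoid) at inference (36.16 M).

The networks run on a small in-package reverse-mode autodiff engine over
NumPy arrays (im2col convolutions via `sliding_window_view` + einsum,
analytic backward passes, Adam). Backward passes are verified against
central finite differences in the test suite.

**Training.** 2D slice-based, restricted by default to
calcification-positive slices (the extreme background imbalance of CAC
masks otherwise swamps the loss). Loss is equally weighted soft-Dice +
binary cross-entropy computed from logits; optimizer Adam, lr 1e-3,
batch 8, no augmentation by default (a flip augmentation is available).
All of these are package defaults exposed in `TrainConfig` — the method
they implement does not prescribe them. Every random draw (init,
shuffling, augmentation) flows from explicit seeds; fixed seeds make
training bitwise reproducible on one platform.

## Cascade

* Heart ROI: largest 26-connected component of the thresholded (0.5)
  heart prediction, tight bounding box, expanded by a 10 mm margin
  (clamped to the volume). An empty heart prediction is an error, never a
  silent full-volume fallback.
* Vessel mask: threshold 0.5; components under `min_component_voxels`
  (default 10) removed. The vessel prior is a morphological dilation by a
  discrete ball of physical radius `prior_dilation_mm` (default 2.0 mm,
  the operationalization of "within or adjacent to" the tree).
* Coordinates: all boxes are half-open `(start, stop)` per axis in the
  canonical (z, y, x) order; crop→map-back round-trips are exact and
  tested, including corner boxes.
* Stage models are pluggable; `OracleModel` wraps a ground-truth mask as
  a probability map, so cascade plumbing is testable independently of
  learning quality (and end-to-end losslessness is asserted exactly).

## Rank-based selective fusion

"Local regions" are connected components of the union of the binarized
(0.5) member maps — 8-connectivity per slice in 2D, 26-connectivity in
3D. Per region and member, three dimensionless scores in [0, 1]:

* **morphological consistency** — area-weighted circularity
  `4πA/P²` of the member's components in the region, with the Crofton
  perimeter estimate (close to true contour length for smooth shapes,
  large for thin/ragged ones), clipped to [0, 1]; components too small to
  have a measurable perimeter count as maximally compact; a 3D mode uses
  the sphericity analogue with exposed-face surface area. Empty
  restriction → 0.
* **topological continuity** — fraction of the member's foreground lying
  in components of at least `s_min` voxels (default 3). Fully fragmented
  speckle scores 0.
* **vessel conformity** — `|mask ∩ prior| / |mask|`. An empty restriction
  scores 0 *before* the no-prior rule, so a member that predicted nothing
  in a region can never be selected for it; with no prior configured,
  non-empty restrictions score 1.

The combined score is a convex combination (default weights 1/3 each).
Members are ranked per region (ties broken by fixed member order:
unet < resunet < attention_unet < unetpp), the top-k (default 2 of 4)
are retained, and members with a combined score of exactly 0 are dropped
regardless of rank. The fused probability on a region is the mean of the
selected members' probabilities (accumulated in float64, fixed member
order, so results are independent of selection order at threshold
knife-edges); the output mask thresholds at 0.5, and with the prior
constraint on, voxels outside the prior are forced to background — an
exact guarantee, which is why the prior-constrained ensemble's
specificity can never fall below soft voting's on decoys planted outside
the prior.

A property worth knowing: ranking is *per region*, so in a region where
only one member fires at all, that member wins the region by default
(its competitors score 0 there). Isolated single-voxel noise that does
not touch any other member's prediction therefore survives selective
fusion unless the prior constraint or the fused threshold removes it;
noise adjacent to a real lesion region is out-ranked and discarded. The
whole rule is verified voxel-exactly against an independent brute-force
reference (BFS flood fill + naive scoring) on thousands of random toy
ensembles.

Soft voting (voxelwise mean of all members, thresholded) is provided as
the comparison baseline, and the ablation harness tabulates single
members, soft voting, selective fusion, selective + prior, and
leave-one-out member ablations.

## Agatston scoring

Per axial slice, 8-connected components of `mask ∩ (HU ≥ 130)` with
projected area ≥ 1 mm² are lesions; each contributes
`area_mm² × w(peak HU)` with the canonical density bins
130–199→1, 200–299→2, 300–399→3, ≥400→4. Risk strata:
0, (0,10], (10,100], (100,400], >400. Scoring runs on the
original-spacing HU grid (masks are mapped back first) so areas reflect
acquisition geometry. A ×(thickness/3 mm) normalization is available but
off by default, the convention for 3 mm gated protocols.

## Metrics

Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) from exact voxel counts. Volume-level numbers
pool counts (micro-average); a per-slice macro-average is offered.
Degenerate conventions are explicit: both masks empty → Dice and
sensitivity 1 (vacuous success); empty reference with non-empty
prediction → Dice 0, sensitivity reported 1 with a `degenerate` flag.

## Synthetic phantoms

`PhantomSpec` describes a cardiac-CT-like volume: soft tissue (40 HU)
with two lung fields (−800 HU), an ellipsoidal heart (60 HU), 2–3
C¹-smooth tubular branches (spline-smoothed random polylines, radius
1–2 mm, 80 HU lumen; 300 HU reproduces contrast-enhanced regimes),
calcified blobs (160–800 HU) attached to vessel walls, bright
extracardiac decoys (700–1200 HU) strictly outside the heart and away
from the dilated tree, and additive Gaussian noise (σ = 10 HU). Two
construction invariants make the acceptance properties decidable rather
than statistical: the calcium HU floor stays ≥ 130 + 3σ (lesions survive
threshold-based scoring under noise), and calcium is constrained to
within `prior_radius_mm` (2 mm) of the tree, so a vessel prior of that
radius covers every lesion and thresholding the noiseless phantom at
130 HU inside the prior recovers the calcium mask *exactly*. Decoys are
deliberately classifier-attractive (HU overlapping calcium) yet outside
the prior — the testbed for false-positive suppression.

Annotations are derived per phantom: one polygon per per-slice calcium
component (sub-pixel contour at 0.5), serialized as the Apple-plist ROI
dialect the parser accepts; parse∘generate is the identity on polygons.

What the phantoms do **not** emulate: real coronary topology, beam
hardening, motion, partial-volume blur, scanner-specific noise textures,
anatomical variation. Passing phantom benchmarks demonstrates that the
pipeline's plumbing, constraints and ensemble logic are correct and that
the models can learn bright-lesion segmentation at desk scale; it says
nothing about clinical-grade accuracy on patient data.

`make_benchmark_suite` derives per-case seeds from a master seed and
splits 80/20. The learning smoke benchmark uses 40 cases of 48³ voxels
at 1 mm, the four variants at depth 2 / base 8 channels, 30 epochs —
sizes chosen so the whole benchmark trains in minutes on one CPU core
while leaving a clear margin above the Dice 0.5 smoke threshold.

## Numerical choices and degenerate inputs

* Polygon rasterization: a pixel is foreground iff its centre is inside
  the closed polygon under the even-odd rule; centres exactly on an edge
  are foreground; zero-area polygons rasterize to nothing; out-of-bounds
  vertices clip with a warning.
* DICOM slices are ordered by the projection of ImagePositionPatient on
  the slice normal, not InstanceNumber (robust to renumbered exports).
* HU values are clamped to [−2048, 8192] after rescale.
* Fusion ties are broken by fixed member order; permuting members changes
  nothing else (tested).
* All thresholds use `≥` so boundary probabilities behave identically
  everywhere.

## Known limitations

* 2D slice models only; no 2.5D/3D variants.
* The NumPy engine targets the tiny benchmark models; reference-scale
  (31–37 M parameter) networks are built and counted but not trained
  here.
* Printed complexity figures for the residual/attention/nested variants
  are matched to within ~1.3% — their exact inner dimensions are not
  derivable from the published figures alone; the baseline U-Net count
  is reproduced exactly.
* Per-artery labels are carried through parsing/rasterization but the
  pipeline segments a single CAC class.
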