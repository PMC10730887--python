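# Methods

This note records the modelling conventions, parameter choices and known
limitations of the `gaitpose` pipeline. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and angle conventions

Image coordinates are 0-based, x rightward, y downward. "Vertical down"
is +y. The camera axis is assumed perpendicular to the subject's sagittal
plane, so all joints of one leg share a common depth and depth cancels in
every angle formula. Segment angles (thigh, calf) are measured from
vertical-down, positive when the distal joint is forward of the proximal
one in the walking direction; the walking direction is a configuration
flag (`walking_sign`, +1 when the subject walks toward +x). Knee flexion
is the angle between thigh and calf vectors, in [0°, 180°].

## Label codec

* **Gaussian convention.** Heatmap values are `exp(-d²/(2σ²))` with σ = 6
  grid pixels. This is the only reading under which the two published
  positive-sample definitions coincide: every integer-lattice cell with
  `d² ≤ d_th = 36` has value ≥ `exp(-1/2) ≈ 0.6065 > 0.6`, and
  `-2σ² ln 0.6 ≈ 36.8`, so the 0.6 heat threshold and the d_th disc
  select the same cells. The test suite asserts this equivalence cell by
  cell.
* **Anchor cell.** The grid-space joint position is the integer anchor
  `(⌊x/4⌋, ⌊y/4⌋)`. Centring the Gaussian and the positive disc on the
  anchor (rather than the continuous position `x/4`) is the only choice
  that makes offsets lie in [0, 1) and decoding (argmax + offset read)
  exactly invert encoding for quarter-pixel coordinates.
* **Limb-guidance masks.** A cell lies on a limb "trunk" iff its scalar
  projection onto the unit edge direction falls within the segment and
  its perpendicular distance to the edge line is ≤ δ/stride (δ = 8 input
  pixels; all masks live on the 1/4-resolution grid). Masks are binary;
  soft directional fields are out of scope. Edges with an invisible
  endpoint give all-zero channels; coincident endpoints additionally warn
  (a degenerate pose).
* **Ties and degenerates.** Decoding breaks argmax ties by first
  occurrence in row-major order; joints whose peak is below the 0.6
  threshold are flagged invisible but still reported with coordinates.

## Network

The published design fixes the branch resolutions and the "four
downsampling, two upsampling" topology but not the per-stage widths,
block counts, cardinality or SE reduction. Defaults here: Focus stem
(space-to-depth /2 + 3×3 conv), three strided SE-ResNeXt stages reaching
/16, FPN lateral fusion back to /4 (the two upsamplings), heads at /4,
and a depth head with two further ×2 upsamplings to full resolution.
Width multiplier 1.0 ("Full") gives 2.31 M parameters and 0.5 ("Lite")
0.58 M — the ~4× ratio of the published variants; exact parameter counts
are not a goal. Heatmap and depth heads end in a sigmoid because their
targets live in [0, 1]; offset and limb-guidance heads are linear
(offsets lie in [0, 1) but train better unsquashed). Initialization is
He-normal from a seeded generator; there are no normalization layers, so
runs are bit-reproducible given the seed.

The tensor engine underneath (reverse-mode autograd, im2col-based grouped
convolution, Adam) is a deliberately small numpy implementation — each
operation reduces to BLAS matmuls, and all of its gradients are verified
against central finite differences in the test suite.

## Loss

`L = (1/mn) Σ [α·SSE_heat + β·SSE_jgs + SSE_depth] + (γ/lk)·SSE_off`,
α, β, γ = 16, 4, 2, where m, n are the heatmap grid dimensions and l, k
the input dimensions (512 at full size). Two published quirks are kept
as printed because they are constant rescalings absorbed by the weights:
the offset term is normalized by the input area even though offset grids
are at 1/4 resolution, and the depth sum runs over the full-resolution
grid while normalized by the heatmap cell count. Offset errors count only
on positive-sample cells; heatmap, limb-guidance and depth are full-grid
MSE (the published labels are dense). A unit error in one heatmap cell of
a 128-grid costs exactly 16/128².

## Training

Adam, weight decay 1e-6, batch 8. Pretraining: lr 5e-4 halved after 50
epochs, grayscale luminance as the depth target when no depth images
exist. Fine-tuning: lr 1e-4 halved every 50 epochs with the stem and
first two stages frozen (the published recipe freezes "a portion of the
backbone" without naming it; the fraction is configurable).
Augmentation: occlusion rectangle (10–25 % of the image side, mean-colour
fill, labels untouched), rotation uniform in ±10° about the image centre
applied coherently to image, depth and keypoints, and mirroring with
probability 0.5 (x-flip plus left/right joint permutation). Dataset
splits are seeded 4:1 partitions with the validation share rounded up
(3588 → 2870/718).

## Gait analysis

* The hip-angle pixel form used is the derivation-consistent
  `arccos(f_x Δy / √(f_y²Δx² + f_x²Δy²))`; the test suite checks it
  against explicit back-projection at arbitrary depth. It is invariant to
  depth and to uniform intrinsic rescaling.
* **Event detection** (not specified by the published method, which only
  consumes the durations): heel strikes are local maxima of each ankle's
  smoothed forward displacement relative to the hip, toe-offs local
  minima, with a 0.4 s minimum separation and a height band keeping only
  extrema in the outer 40 % of the signal range (robust near recording
  boundaries). Deterministic.
* **Stride length** is evaluated at every detected heel strike with the
  leading/trailing roles assigned per striking leg (so the value is
  positive) and averaged over cycles; **speed** = mean stride length /
  mean cycle time. Averaging rather than single-strike sampling was an
  open choice; averaging is less noise-sensitive.
* **Phase symmetry** uses T₀ = 1.2 s, stance/swing weights 0.62/0.38.
  The index is *not* clamped: `√(T₀/T) > 1` for cycles faster than
  normative, so reports with T < T₀ carry a `short_cycle_flag` instead.
  For T ≥ T₀ the index lies in (0, 1], equal to 1 exactly at full
  symmetry and T = T₀ (verified on a dense grid).

## Synthetic walker

The generator emulates a treadmill-style sagittal recording: pelvis fixed
in front of the camera at 3 m, thigh angles follow C¹ half-cosine
stance/swing pulses between −8° and 35°, knee flexion a small stance bump
(6°) plus a large swing bump (60°) — inside the normal walking ranges of
motion (hip −10°…40°, knee 0°…67°). Cycle time 1.2 s, stance fraction
0.62, legs π out of phase; an asymmetry factor rescales the right leg's
stance fraction. Frames render limbs as thick anti-aliased segments,
far-to-near so the near (left) side occludes the far side, with far-side
limbs drawn darker — the shading/occlusion cue by which real sagittal
footage disambiguates left from right. Depth maps encode relative limb
depth in (0, 1] (nearer = larger) over a zero background. Keypoint labels
are always the projected ground truth, also under occluders.

What the generator does *not* emulate: photorealistic appearance,
clothing and lighting variation, camera jitter, soft-tissue motion,
pelvic translation and out-of-sagittal-plane motion. Tests passing on it
therefore validate the geometry, codecs, losses and the analysis chain —
not detection accuracy on real video.

## Problem sizes in the test suite

Unit tests run the narrow-width network at 64–128 px inputs; the
architecture contract is exercised at 128/256/512 for both width
variants. The end-to-end overfit check trains the 0.5-width model on 20
rendered 128×128 frames (batch 8, lr 5e-4) until the decoded keypoints on
those frames reach PCKs@0.5 = 1.0, which takes of the order of 50–80
epochs. These sizes were chosen so the whole suite runs on a single CPU
core; they are far below what real training would use, which is why
detection-accuracy benchmarks are out of scope.

## Known limitations

* Only sagittal-plane quantities are produced; abduction and rotation
  angles are out of scope, as is metric (as opposed to relative) depth.
* Multi-person scenes, part-affinity grouping and sub-pixel peak
  refinement beyond the offset read are non-goals.
* The event detector assumes a roughly periodic walking signal; it
  refuses recordings with fewer than two heel strikes per leg.
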