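# Methods

## The measurement problem

Under visible light, a skin capillary has no contrast of its own: it is
seen only while a packet of red blood cells (RBCs) transits it, as a local
reddening — a depression of the green channel. Functional capillary
density (FCD) therefore cannot be read off a single frame; over a few
seconds every perfused vessel is revealed at least transiently. The
pipeline's premise is that a temporal *minimum-green* projection of a
stabilized video accumulates those transients into a gap-free still, which
a segmentation network can then score like any other 2-D image.

## Pipeline stages and their assumptions

**Stabilization.** Body and operator motion is modelled as a per-frame
integer 2-D translation. The central (W−2m)×(H−2m) crop of frame 0 is the
template (m = 50 px at full scale); each frame is searched exhaustively
over all (2m+1)² positions for the maximum of the zero-mean normalized
cross-correlation, computed on the channel-mean intensity. Ties resolve to
the smallest (y, x) raster position (in practice unique on textured skin).
Sub-pixel motion, rotation and non-rigid deformation are assumed
negligible at the 5 s timescale and are not corrected; drift beyond ±m px
is unrecoverable by construction. An untextured (zero-variance) template
is rejected rather than matched arbitrarily.

**Minimum-G compositing.** Per pixel, the frame with the lowest G value
supplies the full RGB triple; ties go to the earliest frame so the result
is deterministic. The composite's G channel is by construction a lower
envelope of all aligned frames. A mean projection was rejected because a
rarely-perfused vessel would be averaged back into the background.

**Flat-fielding.** Vignetting is modelled as a smooth multiplicative
field. Each channel is divided by its mean-filtered copy (square window,
radius 300 px at full scale — much wider than any vessel, narrower than
the illumination falloff). The denominator is floored at 1 count to guard
dark corners. The dimensionless ratio returns to 8 bits by multiplying
with the channel's global mean (making a constant image an exact fixed
point); a fixed mid-gray gain of 128 is available as an alternative.
Borders use reflection padding by default (replicate optional).

**Contrast enhancement.** Per channel: 256-bin histogram equalization with
min-bin normalisation (the lowest occupied bin maps to 0, the cumulative
histogram above it linearly to [0, 255]; a constant channel is returned
unchanged), then the gamma map v → round(255·(v/255)^γ) with γ = 0.3,
which fixes 0 and 255 and brightens mid-tones strongly. Equalization runs
first; the order matters and is fixed.

**U-Net.** A standard depth-d encoder/decoder with skip connections, two
3×3 same-padded convolutions + ReLU per level, 2×2 max pooling, and
nearest-neighbour upsampling followed by a 3×3 convolution in the decoder;
a 1×1 convolution and sigmoid produce per-pixel probabilities on the input
grid. The network, its backpropagation and the Adam optimizer are
implemented directly in numpy (im2col convolutions); the backward pass is
verified against central finite differences to ~1e-6 relative error. The
full-scale configuration is depth 4 / 64 base channels, 512×512 patches,
batch 16, 50 epochs; desk-scale experiments use depth 3 / 16 base channels
on 64×64 patches, which train in seconds on one CPU. Loss is binary
cross-entropy by default (Dice and BCE+Dice available); the optimizer and
learning rate (Adam, 1e-3) are this package's defaults, chosen because the
original training protocol does not document them. Inputs are normalized
by /255; masks are {0, 255} with 255 = capillary.

**Tiled inference.** Windows (default 512 px) slide row-major with a 50 px
stride in both axes; the last window of each row/column is clamped to the
image edge so every pixel is covered without fabricating border context.
Overlapping probabilities are averaged per pixel (max available), then
thresholded at 0.5 with `p ≥ t` so that raising the threshold can only
remove mask pixels.

**Quantification.** Connected components under 8-connectivity (default, so
thin diagonal vessels remain single regions; 4-connectivity available),
labeled in raster order of first-encountered pixel. No minimum-size filter
by default. Variables: number N, total area A (px), average area A/N
(undefined — `None`, never 0 — when N = 0); physical areas via
(1.85 μm)² per pixel. Calibration to manual-annotation scale uses
through-origin least squares b = Σxy/Σx² (the printed form of the
reference regressions has no intercept; an intercept option exists but is
off by default), with Pearson r stored as a fit diagnostic only; inversion
is x̂ = y/b.

**Evaluation.** Pixel level: the six standard confusion-derived metrics,
with every 0/0 reported as missing. Region level: a ground-truth region is
TP if ≥1 of its pixels is predicted, FN otherwise; a predicted region
disjoint from all ground-truth foreground is FP. TP is counted in
ground-truth-region units and FP in predicted-region units; precision
TP/(TP+FP) deliberately mixes those units — this matches the reference
convention for thin structures, and is the reason no region-level TN or
IoU is defined. One predicted blob touching k ground-truth regions makes
all k TP. Metrics across multiple images are averaged per image with equal
weights, not pooled. Bland–Altman: differences per an explicit sign
convention (default prediction − ground truth; the convention is
configurable because published agreement intervals are ambiguous about
sign), limits of agreement = mean ± 1.96 sample SD (ddof = 1).

## The synthetic scene generator

The generator is the package's test bed and defines the study conditions.
It emulates, per seeded scene: a smooth skin-coloured background field with
fine static texture (texture is required for template matching to lock
on); tortuous vessels as bounded-curvature random walks of unit step,
stroked with a per-vessel width drawn from 2–6 px (the ~10 μm outer
diameter of a capillary is ≈5.4 px at 1.85 μm/px); RBC packets as arc-
length intervals (15–30 % of vessel length) advancing at a constant
per-vessel speed of 2–6 px/frame with wrap-around, depressing G strongly
and B mildly (default contrast 60/255 — the real RBC contrast is
undocumented, so it is a config parameter); a fraction of vessels
(default 0.5) perfused intermittently, the rest filled in every frame;
radial multiplicative vignetting; per-frame integer jitter with
replicate-edge fill (frame 0 at zero offset, so ground truth lives in
template coordinates); static distractors (colour-neutral stains, bright
sweat-gland dots, dark hairs) that never enter the ground-truth mask; and
mild per-frame Gaussian sensor noise (σ = 2 counts), small against the RBC
contrast so a covered pixel's G minimum is strictly attained during a
transit. Vessel placement retries up to 20 times to keep footprints
disjoint, then accepts overlap; the emitted region count is always the
actual connected-component count of the emitted mask.

It does **not** emulate: photorealistic skin, 3-D vessel geometry or depth
blur, pulsatile or variable flow, rolling shutter, chromatic aberration,
or lossy video compression. Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the modelled degradations
(jitter, vignetting, intermittent perfusion, distractors) — not
performance on real skin recordings, whose annotation ambiguity and
optical blur are outside the model.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen to
exercise every code path: scenes of 288×224 px × 30 frames with 7 vessels,
a 4 px stabilization margin, flat-field radius 20–40 px, and a depth-3 /
16-channel U-Net trained for 8 epochs on 48 patches of 64×64 px — about
half a minute end to end on one CPU. The full-scale parameters
(4000×3000×150 frames, margin 50, radius 300, depth-4/64 network, 512 px
windows) are the package defaults and scale linearly in pixels × frames.

## Known limitations

- Stabilization is integer-translation only; a scene that drifts more than
  the margin, or rotates, mis-aligns silently within the searched window.
- The numpy U-Net favours transparency over speed; at the full 512-px /
  depth-4 scale, training is orders of magnitude slower than a GPU
  framework and memory for im2col grows with window size.
- The region-level precision mixes counting units (see above); compare it
  only with numbers computed under the same convention.
- Shipped calibration slopes are instrument- and protocol-specific; they
  are defaults to be refit, not constants.
- With vanishing foreground, several metrics are undefined; callers must
  handle `None` rather than assume 0.
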