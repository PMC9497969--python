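# Methods

`fluorocad` implements a two-step computer-aided-diagnosis (CAD) flow for
wide-field fluorescence endoscopy of the esophagus: (1) a small CNN rejects
frames showing a normal esophagus or imaging artifacts and selects frames
with suspicious bright lesions; (2) on selected frames the fluorescence
target is segmented and quantified by its target-to-background (T/B) ratio
— the mean fluorescence intensity over the target divided by the mean over
a 30-pixel-wide background band around it.  Because pixel-level lesion
annotation is rarely available in this setting, the segmentation network is
trained on *weak labels* produced by a Chan-Vese level-set segmenter from
frame-level diagnoses only.  This note records the models, the parameters
that matter, and the numerical choices behind each stage.

## Synthetic SFE frames

Scanning-fiber-endoscope (SFE) videos show a circular field of view (FOV):
fluorescence is recorded on the green channel and tissue reflectance on the
blue.  The simulator (`fluorocad.simulate`) emulates the statistical
structure of such frames so every stage is testable without clinical data:

* **Suspicious frames** carry 1–3 "patchy" bright lesions: a low-frequency
  Gaussian random field is added to a Gaussian radial envelope and
  thresholded, giving irregular, fragmented boundaries like those of
  topically labeled neoplasia.  Lesion intensity is drawn from
  [0.60, 0.90], the tissue background from [0.25, 0.45] (on the [0, 1]
  scale of standardized frames), so the planted T/B ratio spans roughly
  1.3–3.6 around the values reported for fluorescence-labeled Barrett's
  neoplasia.  The config refuses settings where the lesion minimum does not
  exceed the background maximum, so planted contrast is always positive.
* **Artifact/normal frames** carry one of the four artifact families a
  frame-selection model must reject — saturation (a region pinned at 1.0),
  dye pooling (a diffuse bright pool hugging the FOV border), air bubbles
  (bright annuli), an instrument (dark occluding disk with a bright rim) —
  or plain tissue.  Their lesion mask is empty by construction.
* Additive Gaussian noise (default sigma = 0.02) is applied before the
  final clip to [0, 1]; with sigma = 0 the construction is exact, which the
  exactness tests rely on.  All randomness flows from one integer seed.

What the simulator does **not** model: realistic esophageal texture,
vignetting, motion blur between frames, and the 30 Hz temporal correlation
of SFE video.  Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline, not clinical performance.

## Preprocessing

Frames are resized to a square working size (bilinear; masks as binary
indicators), scaled by the bit-depth maximum (255 or 65535) into [0, 1],
and given an explicit FOV mask — derived, when absent, as the pixels with
any nonzero channel after a one-pixel closing, since SFE frames are black
outside the scan circle.  Dual-probe frames (two fluorescence probes on red
and green, shared reflectance on blue) are split into two single-probe
frames, each with its probe mapped to green; the segmentation path consumes
the fluorescence channel as grayscale.  Standardization is idempotent.

## Chan-Vese segmentation

`fluorocad.chanvese` minimizes the two-phase piecewise-constant energy

    E(phi) = mu * Length({phi = 0}) + nu * Area({phi > 0})
           + lambda1 * sum_{phi > 0} (I - c1)^2
           + lambda2 * sum_{phi <= 0} (I - c2)^2

restricted to the FOV, with c1/c2 the region means (recomputed every step,
so the reported energy is the reduced functional).  Numerical choices:

* **Length** is the exact count of 4-neighbor boundary edges of the sharp
  partition.  This makes the discrete energy cheap and self-consistent and
  gives the zero-residual identities the tests assert.
* **Evolution**: explicit gradient descent on phi with a smoothed Dirac of
  width `eps` (arctan Heaviside), curvature by central differences.  The
  force is normalized to unit maximum so `dt` is a pixel-scale step — the
  raw Dirac-weighted force is orders of magnitude too small to move the
  contour when the two phases start with nearly equal means, as they do
  from the default checkerboard.
* **Monotonicity by construction**: each step is accepted through a short
  line search over multiples of `dt` that strictly lowers the reduced
  energy.  When no multiple does (a fine checkerboard with mu > 0 can trap
  strict per-step descent along a single direction), one ICM parity sweep
  — flipping every pixel whose individual flip strictly lowers the same
  energy, swept per checkerboard parity so 4-neighbors never interact —
  serves as the escape move, after which phi is re-synced to a signed
  distance function.  The energy trace is therefore non-increasing at
  every iteration, which the tests check to 1e-9.
* **Stopping**: mean |delta phi| per FOV pixel below `tol` (1e-3), or ten
  consecutive iterations with an unchanged partition (phi can drift inside
  the smoothing band after the partition has settled), or `max_iter` (500).
  phi is re-initialized to a signed distance every 50 iterations.
* **Degenerate input**: a constant image inside the FOV returns an empty
  mask with a warning rather than an arbitrary partition.
* **Orientation**: the brighter region is reported as the target (swap if
  c1 < c2), the correct convention for fluorescence.

Defaults mu = 0.2, nu = 0, lambda1 = lambda2 = 1, dt = 0.5, eps = 1,
tol = 1e-3 follow common Chan-Vese practice for [0, 1] images.  On
piecewise-constant images the minimizer coincides with the midpoint
threshold between the two levels, which is the independent oracle used
throughout the tests.  A caveat the fixed-point test reflects: with mu > 0
the *discretized* boundary of a curved region (e.g. a rasterized disk) is
not exactly stationary — single-pixel smoothing moves genuinely lower the
discrete energy — so exact fixed-point checks use axis-aligned rectangles,
and curved targets are recovered to IOU ≈ 0.99 rather than exactly.

### Weak labels

The label-generation workflow warm-starts the level set from an Otsu
threshold of the fluorescence channel (`init='from_mask'`), letting the
energy descent refine an already-near contour; frames whose segmentation is
degenerate or empty are flagged `label_quality=low` in the manifest rather
than silently included.

## T/B quantification

The background band is built from the exact Euclidean distance transform:
band = {0 < d(x, target) <= width} within the FOV, identical to dilation by
a Euclidean disk of radius `width` (default 30 px on the standardized grid)
minus every target pixel — so overlapping bands of nearby lesions never
include target pixels.  T/B = mean(target) / mean(band).  Means over
constant regions are returned exactly (no summation rounding), so a uniform
image yields T/B = 1.0 identically.  Per-frame quantification defaults to
one ratio over the union mask; a per-lesion mode quantifies each
8-connected component, dropping components under 25 px as speckle.

## Networks

Both networks run on `fluorocad.nn`, a small numpy reverse-mode autodiff
library written for this package (tensors with a backward tape; dense and
depthwise strided convolution; batch normalization; global average pooling;
nearest upsampling; Adam).  Everything is float32 and seeded, so training
runs are bit-reproducible on one device.

* **Frame classifier**: a width/depth-scalable backbone of
  inverted-residual blocks ("mobile_like") or separable-conv blocks with
  linear skips ("xception_like"), then global average pooling and two fully
  connected layers to a single suspicious-frame probability.
* **UNet segmenter**: the same backbone as encoder; the decoder upsamples
  and concatenates the symmetric encoder feature at every scale, ending in
  a 1x1 conv to two classes at full resolution.  Argmax ties resolve to
  background.
* **BiSeNet segmenter**: a three-conv spatial path at 1/8 resolution plus
  the backbone as context path, attention refinement (channel attention) on
  the last two context stages, a global-average context tail, and a feature
  fusion module (concat, 1x1 conv, residual channel attention); scores are
  upsampled 8x to full resolution.  Requires backbone depth >= 4.

Training uses Adam with the learning rate multiplied by 0.8 every 10 epochs
(`lr(e) = lr0 * 0.8^floor((e-1)/10)`), binary cross-entropy for the
classifier and pixel-wise categorical cross-entropy for the segmenters, and
early stopping that restores the checkpoint with the best validation
accuracy (patience 15 epochs).  ImageNet-style pretrained initialization is
deliberately not bundled (it requires a download; for single-channel
fluorescence input it is also of limited value); the checkpoint format (npz
weights + JSON spec sidecar) leaves room for external initialization.

Grad-CAM weights the final backbone feature map by the spatially averaged
gradient of the class score, rectifies, upsamples to the frame grid and
max-normalizes; an all-zero gradient (degenerate constant model) yields a
defined all-zero map.

### Desk-scale recipes

`fluorocad.desk` fixes the problem sizes used by the tests and the
acceptance script: 96 x 96 frames; 400/100 train/validation frames for the
classifier (width multiplier 1.0, depth 3, <= 20 epochs, geometric
augmentation only — the one family that removes the positional and size
biases of a small corpus and measurably improves out-of-family
generalization); 200/50 phantoms for the segmenter (width 0.5, depth 3,
<= 10 epochs, lr 2e-3).  These sizes train in minutes on one CPU while
leaving clear margins over the accuracy floors the tests assert.

## Augmentation

Three independent families: geometric distortion (flips, rotation sampled
in [0, 90] degrees, scale and shift within ±10%), brightness/contrast, and
blur/noise (motion blur by a random-angle line kernel of 3-9 px, Gaussian
blur sigma in [0.5, 2], additive noise sigma up to 0.05 — magnitudes chosen
mild so labels stay valid).  The identical geometric transform is applied
to image and mask; flips and axis rotations are exact array operations
(true involutions); arbitrary-angle warps interpolate the image bilinearly
and the mask as a bilinear indicator thresholded at 0.5, which keeps the
mask binary while tracking the image's sub-pixel boundary placement
(nearest-neighbor sampling loses ~2% IOU on patchy boundaries).
Photometric and blur/noise transforms never touch the mask.

## Evaluation statistics

Sensitivity, specificity, precision and accuracy come from explicit
confusion counts; a metric with a zero denominator is reported as
undefined, never 0.  ROC/AUC uses the threshold sweep with trapezoidal
integration, which equals the Mann-Whitney U statistic with ties counted
one half — verified against brute-force pair counting.  IOU of two masks
defines the both-empty case as 1.0 (needed for artifact frames where truth
and prediction are both empty); mIOU averages the target-class and
background-class IOUs per frame, then across frames.  Model comparisons use
the classical paired t-test (n-1 df); the one-tailed variant reports half
the two-tailed p on the hypothesized side, and zero-variance differences
raise a degenerate-test error instead of returning a spurious p.

## Pipeline

`run_cad` standardizes each frame, scores it with the classifier, and only
frames at or above the selection threshold (default 0.5) reach
segmentation and T/B — rejected frames never touch Step 2, which is the
efficiency mechanism of the two-step design.  Reruns with the same models
and seed are bit-identical.  Unreadable frames are logged, skipped and
counted.  `generate_weak_labels` applies the Chan-Vese stage to frames
flagged suspicious either by dataset labels or by the Step-1 model,
recording provenance and label quality per frame.

## Known limitations

* The simulator's lesions are homogeneous in intensity; real fluorescence
  targets show internal intensity gradients and scattering halos, which
  would lower both Chan-Vese and CNN accuracy relative to the figures the
  desk experiments produce.
* The numpy networks are CPU-bound and desk-sized; the architecture specs
  scale to full-size configurations, but no claim is made about real-time
  throughput.
* Chan-Vese is two-phase: frames with both a lesion and a bright artifact
  would be segmented as one bright phase.  The pipeline relies on Step 1
  rejecting artifact frames before segmentation, as the two-step design
  intends.
* T/B means include saturated pixels; no exclusion rule is applied.
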