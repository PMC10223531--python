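# Methods

## Problem

Contactless dorsal hand vein (DHV) biometrics matches the subcutaneous vein
pattern on the back of the hand, imaged in near infrared where hemoglobin
absorbs strongly: the hand scatters light back and appears bright, the veins
and the background appear dark.  Matching is performed on a region of
interest (ROI), an oriented square patch of the dorsum.  With unconstrained
capture — free hand pose, rotation, pitch, cluttered desks and clothing in
the background — classical silhouette-based ROI extraction breaks down, so
the ROI is anchored instead on the four finger-web valleys (the skin
junctions between adjacent fingers) located by a learned keypoint detector.

This package implements that pipeline end to end: a synthetic NIR hand
generator with exact valley annotations, heatmap-based keypoint detection
with a lightweight residual encoder-decoder, divergence-based supervision,
Soft-argmax decoding, keypoint-anchored ROI geometry, the strict
pixel-threshold accuracy metric, and two classical contour baselines for
comparison.

## Synthetic data generator

No public dataset of annotated unconstrained DHV images exists, so the
package generates its own study conditions.

**Geometry.**  A hand is one palm ellipse plus five finger capsules whose
roots sit on a shallow arc above the ellipse; a "knuckle bar" capsule just
below the root line and two shoulder capsules blend the finger bases into
the palm so the silhouette has no spurious concavities.  Each web valley is
*constructed*, not annotated: it is the apex of the wedge between two
adjacent capsules, i.e. the intersection of their facing boundary lines.
All transforms — pitch foreshortening (vertical compression), mirroring for
left hands, global rotation about the palm center — are applied to the
skeleton before the valleys are solved, so the labels are exact for the
rendered silhouette and rotation acts on the keypoints as an exact rotation
(verified to < 0.5 px, in practice ~1e-13).

The thumb is rendered short, thick and strongly splayed and the little
finger slim, as on real hands; this asymmetry is what lets a detector (and a
human) tell P0 (thumb-index web) from P3 (ring-little web) after mirroring.

**Parameter ranges** (fractions of image size unless noted) are drawn per
sample: palm center x 0.42-0.58, y 0.55-0.68; palm semi-axes 0.13-0.165 and
0.19-0.245; rotation ±35°; per-finger splay angles around
(-52, -19, -2, 15, 30)° with 3-4° jitter; foreshortening 0.8-1.0; left/right
50/50; 4-9 veins; additive Gaussian noise sigma 3-7; occlusion with
probability 0.3 covering 5-30 % of the hand.  Draws whose valleys are not on
the silhouette boundary (wedge apex buried in the palm, fingers intersecting,
valley outside the frame) are rejected and resampled.

**Rendering.**  Intensities follow the NIR convention: hand 140-235,
clean background 10-60, veins darken by 20-60.  The hand's shading, texture
and vein strokes are generated in a canonical hand frame and warped with the
hand, so rotating the hand rotates its texture (the background stays in the
scene frame).  Background modes: *clean* (uniform + mild smooth variation),
*glare* (bright fluorescent-lamp blobs), *clutter* (hard-edged rectangles
and ellipses of varied intensity, which defeat global thresholding).  Mean
background variance is ordered clutter > glare > clean by construction.
Silhouette edges are antialiased through a signed-distance field; the same
field, supersampled locally, is used to verify that every keypoint lies
within 2 px of the silhouette boundary (the web crack is narrower than one
raster pixel near the apex, so a plain-raster measure cannot resolve it).

**What the generator does not model:** real vein topology, skin texture,
specular highlights, rings and jewellery, motion blur, perspective (only an
affine pitch squash), and inter-person correlation of hand shape.  Passing
tests on this data show the pipeline is correct and that the learned
detector beats silhouette baselines under clutter; they do not certify
accuracy on real NIR captures.

## Network

The detector is a lightweight encoder-decoder regressing a 4-channel
heatmap stack (one channel per keypoint) at input resolution:

* stem: 3x3 convs 1→20→10 channels, edge padding (2010 parameters);
* encoder: four residual blocks; each halves resolution with a 3x3 stride-2
  conv, and a 1x1 stride-2 shortcut projection is added back before the
  final ReLU, down to 1/16 resolution (batch norm + ReLU throughout);
* decoder: four 2x bilinear upsampling steps; a 1x1 conv reduces decoder
  channels and the matching encoder output is fused through its own 1x1
  conv by elementwise addition (BN + ReLU after the sum);
* head: 1x1 conv to 4 channels.

Stage widths default to (16, 32, 64, 128), giving 325,570 parameters
(1.30 MB fp32) — about 24x fewer than the classic U-Net baseline
(7.77 M parameters) built with double-conv stages, max pooling,
transposed-conv upsampling and concatenation skips.  Ablation variants
drop the shortcut projections or replace bilinear upsampling with 2x2
stride-2 transposed convolutions.

The layers are implemented in NumPy with explicit backward passes
(`veinroi.nn`): im2col + GEMM convolutions, batch norm, bilinear upsampling
as separable dense operators, max pooling, transposed convolution, Adam and
a step-decay schedule.  Gradients are verified against central finite
differences and exact adjoint identities in the test suite.

## Supervision

Labels are unnormalized Gaussians with peak 1 at each keypoint
(sigma = width/32 by default).  Three terms supervise the output:

* **MSE** on raw heatmaps — value agreement;
* **Jensen-Shannon divergence** between softmax-normalized prediction and
  label channels — shape agreement; pushes the output toward a unimodal
  Gaussian and suppresses spurious secondary peaks.  Natural logs, so
  JS ≤ ln 2; KL terms floor the denominator at 1e-12;
* **Euclidean distance** between the decoded coordinates and the label, in
  heatmap pixels — direct, differentiable localization.  The decode used by
  the loss is the same windowed Soft-argmax as inference: the expectation
  sum_i softmax(beta x)_i · i evaluated in a 9x9 window around each
  channel's argmax, with the window-adaptive beta = 10/range.

The combined loss is the unweighted average of the enabled terms.  Two
numerical traps motivate the windowed coordinate term.  A *global* softmax
over a mostly-empty map is pinned to the grid center by its uniform floor,
so the term's value freezes and its gradient degenerates to a constant tilt
that fights blob formation; and the gradient scales linearly with beta, so
at decode-sharp betas it is ~1e4 times the MSE gradient and drowns the
heatmap terms.  Windowed, the term both converges fastest of the three in
isolation and accelerates the combined objective.

## Decoding

Raw channels decode with Soft-argmax.  Over a full, mostly-empty map the
softmax floor biases the expectation toward the grid center, so
`decode_stack` refines within a 9x9 window around the hard argmax with
beta = 10/range; this recovers keypoints to < 0.3 px across label sigmas
1-8.  Confidence is the channel's peak value.  Ties in hard argmax break to
the smallest row, then column.

## ROI geometry

From keypoints P0..P3: the X-axis runs along P1→P3, the origin is the
midpoint of P1P3, |P1P3| is the unit length, and the Y-axis points
perpendicular into P0's half-plane (P0, the thumb-side web, sits wrist-ward
of the P1P3 line, so the square lands on the dorsum).  The ROI center is
origin + (5/6)|P1P3| along +Y and the square's side is |P1P3|.  Cropping
resamples bilinearly into a square (default 128), zero-fills out-of-bounds
samples and reports the in-bounds coverage fraction.  The construction is
similarity-equivariant to 1e-9 relative error.  Which web is "P0" is a
labelling convention; had P0 denoted one of the inner webs, the Y
orientation rule would flip.

## Evaluation

A keypoint is correct when its Euclidean distance to the label is strictly
below the threshold; distance equal to the threshold counts as incorrect.
The canonical rule is 40 px at 1080-px annotation height (3.7 % of height);
at working resolutions the package scales it proportionally (5 px at 128,
2.5 px at 64).  Accuracy is counted per keypoint, not per image.  The
heatmap peak value serves as a confidence score; ROC analysis labels each
prediction by its correctness flag and integrates by the trapezoid rule.

## Classical baselines

Both binarize with Otsu's threshold, keep the largest connected component
(rejected unless it fills 4-60 % of the frame) and trace the outer contour.

* **Convex hull / convexity defects:** the four deepest defect far points,
  with depth at least 5 % of the hand bounding-box diagonal.
* **Centroid distance:** the smoothed contour-to-centroid distance profile
  (window 2 % of contour length) has one prominent maximum per fingertip;
  the five fingertips are the minimal-span circular window of five
  prominent maxima, and the valleys are the deepest minima in its four
  gaps.  Selecting instead the four minima nearest the centroid — the
  literal reading of the method — picks up flank junctions on our
  silhouettes and loses about half the clean-background accuracy, so the
  fingertip-gap rule (the convention of the classical DHV literature) is
  used.

Baseline outputs carry no handedness, so evaluation matches them to labels
by Hungarian assignment before scoring.  Failures (no contour, too few
defects/minima) are structured results, not exceptions, and score as
incorrect keypoints.

## Desk-scale study conditions

Reference experiments (`veinroi.experiments`) run at 64x64 with the 2.5 px
threshold: 300 mixed-condition images, 8:2 split, 200 epochs at batch
size 4 (12,000 update steps), Adam 1e-3 with x0.5 step decay every quarter
of the run, flips/brightness/contrast/hist-eq augmentation, and the model
checkpointed at its best validation accuracy.  The supervision ablation
compares the four loss settings over three seeds at a smaller equal budget
(100 images, 20 epochs).
Classical baselines run at 256x256 with the 10 px threshold (the same
fraction of image height); the same seeds generate the same hands at both
resolutions.  The "clean" baseline condition disables occlusion, emulating
a hand on a clean platform; "cluttered" keeps the full occlusion mix.
Small batches are used deliberately: on one CPU they buy the optimizer
several thousand update steps at this problem size, which this optimizer
needs to converge.

## Known limitations

* The NumPy training loop is orders of magnitude slower than a GPU
  framework; the reference run is scaled accordingly (image size, epochs).
* The palm-ellipse term of the silhouette field is a first-order signed
  distance approximation (exact for the capsules).
* Foreshortening is an affine squash, not a perspective projection.
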