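# Methods

## Problem and scope

`polypnet` implements a complete desk-scale version of a grayscale-first
colorectal-polyp screening pipeline for endoscopy stills: luma
preprocessing, an anchor-grid single-stage CNN detector, a two-class CNN
classifier (neoplastic vs hyperplastic), the center-point evaluation
protocol with exact paired statistics, and a synthetic scene generator
that stands in for clinical data.  The package targets the methodology —
architectures, decoding rules, cutoffs, metrics and tests — not the
clinical accuracy figures, which are properties of hospital image sets
that cannot be redistributed.

## Grayscale conversion

Luma is a weighted channel sum, `Gray = cR·R + cG·G + cB·B`, rounded
half-away-from-zero and clipped to 0–255.  Two coefficient sets are
built in:

* `standard` (default): ITU-R BT.601, (0.299, 0.587, 0.114).
* `legacy`: (0.229, 0.587, 0.117), a variant circulating in some
  published detection systems.  Its weights sum to 0.933, so it darkens
  every frame by ~7%; it looks like a transcription of BT.601 and is kept
  only for fidelity with models trained under it.

The default is the standard set because the conversion is described
everywhere as BT.601; the legacy set is selectable (`--mode legacy`).

## Numerical engine

No GPU framework is used: the networks run on a compact numpy engine
(`polypnet.nn`) with explicit forward and backward passes — tap-wise
BLAS GEMMs for convolution (a 3×3 'same' convolution is nine shifted
matrix products, which avoids materialising im2col buffers that would
run to hundreds of MB at 480×640×16), strided non-copying window views
for pooling, standard batch-normalisation backward algebra, and Adam.
Convolutions use the strict signal-processing orientation (kernel
flipped), so a layer's output equals the textbook double sum evaluated
with the same weight array; for learned kernels the orientation is
immaterial.  Every backward pass is validated against central finite
differences in the test suite; all arithmetic is float32 with float64
reductions in the activations.

## Detector

Input 128×128 (1 or 3 channels); three multi-kernel convolution blocks
with 2×2/2 max pooling (16, 32, 64 filters; 128→64→32→16), three further
blocks at 128 filters, then a 1×1 convolution to 24 channels on the
16×16 grid.  The multi-kernel block runs 3×3, 3×1 and 1×3 kernels in
parallel and sums their responses elementwise; summation is the only
combination rule consistent with a block whose published output channel
count equals its filter count (concatenation would triple it).  A
concatenate-then-1×1-project variant exists behind `combine="project"`.

The 24 head channels are read as 8 anchors × (objectness, x-offset,
y-offset).  The anchor priors, in original-frame pixels, are (16,16),
(32,32), (24,48), (48,24), (60,80), (108,72), (216,144), (180,180).
Anchors up to 216 px cannot refer to the 128×128 network input, so cell
coordinates map to the native frame by (W/16, H/16); this is an
interpretation, recorded as such.  Decoding: for each cell and anchor
with sigmoid(objectness) ≥ cutoff (default 0.2), the center is the cell
origin plus sigmoid-squashed offsets times the cell stride; width and
height are the anchor dims; boxes are clipped to the frame; greedy
IoU-0.5 suppression is applied by default and can be disabled.

Training targets (the training scheme of the reference system is
unpublished): each ground-truth box activates the best-IoU anchor (ties
to the lowest index) in the cell containing its center, with the
fractional center position as offset target.  The loss is binary
cross-entropy on objectness — positive and negative entries averaged
separately and combined 5:1, since one positive among 2047 negatives per
frame would otherwise vanish — plus squared error on the sigmoid offsets
over positives.  The objectness head bias starts at −2 so an untrained
network emits nothing at the 0.2 cutoff.  Default recipe: Adam, lr 1e-3,
batch 16; all configurable, nothing hard-coded.  After training, one
statistics-only forward sweep settles the batch-norm running averages,
which otherwise lag badly after short runs.

## Classifier

Input 480×640 (H×W of the landscape frame; portrait inputs are
transposed, never stretched); six multi-kernel blocks (16, 16, 32, 32,
64, 64 filters) with 2×2 pools at strides 2, 2, 3, 3, 3, 2, reaching
2×3×64, then a fully-connected layer to two logits and softmax.  The
published table lists the last pool at stride 1, but 4×6 → 2×3 requires
stride 2; the printed output shape is treated as binding.  The stride-3
pools produce the characteristic 40×53 and 13×18 maps
(floor((D−2)/3)+1).  A frame is called neoplastic when
softmax(neoplastic) ≥ 0.5; the exact tie resolves to neoplastic, the
clinically conservative direction (it favors resection review over
leave-in-place).  Class imbalance is handled by inverse-frequency loss
weights (configurable), mirroring imbalanced clinical verification
splits.  The convolution stack is resolution-agnostic, so the same
topology builds at reduced input sizes with the dense layer's fan-in
derived from the actual pooled map; whether the original system
classified full frames or detector crops is unstated, and both are
supported.

## Evaluation protocol

Detection uses the center-point criterion: a prediction is a true
positive iff its center lies inside (edges inclusive) some ground-truth
box; a false negative is charged only when no prediction box appears at
all (a per-GT-box mode exists for multi-polyp frames).  There is no
box-level true negative since every polyp frame contains a lesion.
Image-level accuracy is correct detections over polyp frames; for
normal frames "correct" means zero boxes emitted.

Classification metrics come from the 2×2 confusion matrix with
neoplastic positive: Acc = (TP+TN)/total, Prec = TP/(TP+FP),
Rec = TP/(TP+FN), F1 = 2PR/(P+R), F2 = 5PR/(4P+R), reported as
1-decimal percentages.  (One published formula table prints
Acc = (TP+FN)/total; the published metric values are only consistent
with (TP+TN)/total — e.g. (118+31)/180 = 82.8% — so the standard
formula is implemented and the printed variant treated as a typo.)
NPV = TN/(TN+FN), quoted at integer percent against the 90%
diagnose-and-leave threshold.  AUC is the rank statistic with ties
averaged.

Paired arm comparisons use the exact McNemar test,
p = min(1, 2·P(X ≤ min(a,b))) for X ~ Binomial(a+b, ½): the observed
discordant counts are 0–19, far below where the χ² approximation is
defensible, and the exact form reproduces the published p = 0.25 for
(0, 3).  Proportions carry Clopper–Pearson exact 95% CIs; this choice
reproduces both published intervals, where Wilson misses one endpoint
(95.1 vs 95.2 for 843/900).  Wilson remains available as an option.

Size stratification splits records at the tight-box pixel area of the
largest lesion; "below" means strictly less than the threshold, so a
40×40 = 1600 px lesion sits in the at-or-above stratum of the 1600
threshold, matching the "less than 1600 pixels" phrasing of the
analyses the thresholds come from.

## Synthetic scenes

The generator emulates 640×480 colonoscopy stills just closely enough to
exercise every code path: a luminance field with an off-center dark
lumen, corner vignette, angular wrinkle ridges bent by smoothed noise,
small saturated specular discs and sensor noise, colored by a
white-light-like (red-dominant) or narrow-band-like (red-suppressed,
green/blue-boosted) per-channel gain triple.  Polyps are shaded
elliptical protrusions; the wall texture beneath a lesion is blurred
before compositing (the protrusion occludes it), and the brightness bump
is strictly positive inside the ellipse so the composited-pixel mask is
exactly the filled ellipse and the returned box is its tight extent.
Semi-axes are solved from the requested tight-box area with a quadratic
correction for pixel sampling; rendered box areas land within ±10% of
target, which lets datasets straddle the 1600/1800 px analysis
thresholds deliberately (default area range 800–6400 px).

The two texture classes mirror the optical taxonomy used clinically:
"neoplastic" lesions carry sparse dark branched random-walk strokes
(tubular vessels; coverage is held near 10–20% because denser strokes
invert the texture's photometric signature), "hyperplastic" lesions a
jittered grid of uniform light dots.  A blind statistic — the third
moment of the high-pass residual inside the lesion box — separates the
classes at ≥95% in the tests, certifying the classification task is
learnable without reference to any trained model.

Defaults mirror the study conditions: 640×480 frames, balanced class
mix, 0.5 negatives fraction for detection-style sets (the clinical test
design used 900 polyp and 900 normal frames), balanced palettes, lesion
areas drawn uniformly from 800–6400 px.  Everything derives from one
integer seed; identical spec + seed yields bit-identical frames and
files.

The generator does not attempt hemoglobin spectra, lens distortion,
motion blur, stool/fluid artefacts, or inter-patient variation.
Passing the synthetic end-to-end thresholds therefore demonstrates that
the pipeline's machinery works and the tasks are learnable — it says
nothing about performance on clinical images.

## Experiment harness and problem sizes

`run_experiment` reproduces the two-arm protocol: one dataset, a
stratified 75/25 train/test split, color and grayscale arms trained and
evaluated independently, paired exact McNemar on their per-frame
outcomes, and area stratification at 1600/1800 px.  Reports embed the
config hash and seed and regenerate bit-identically.

Desk-scale choices, made once: the standard experiment uses 400 frames
(300 polyp / 100 normal), 8 detector epochs and 6 classifier epochs;
the classifier trains on ground-truth lesion crops (20% margin) resized
to 192×256 — crops keep the texture at near-native scale, where
full-frame downsampling would erase the dot/stroke signature, and the
cheapest full-resolution alternative is an order of magnitude slower on
a single CPU.  The acceptance script runs a 240-frame variant of the
same protocol.  Five-fold utilities (`make_folds`) support
cross-validation layouts; the published protocol is ambiguous about
whether its hospital sets were split 5-fold or held out wholesale, and
the harness supports both topologies.

## Known limitations

* Normal-frame specificity in the short synthetic runs (tens of
  percent) trails a clinically trained system by a wide margin: with
  6–8 epochs the objectness head has not yet suppressed all background
  responses at the 0.2 cutoff.  Polyp-frame accuracy and class accuracy
  saturate first; specificity needs longer schedules.
* The per-anchor channel semantics, loss, and multi-kernel combination
  rule of the reference system are unpublished; this package's choices
  are documented interpretations, consistent with the printed shapes.
* Batch-norm inference statistics come from short runs; the
  recalibration sweep mitigates but does not eliminate small-batch
  drift.
* The annotation schema is box-based; mask ground truth is supported
  only through conversion (`mask_to_bboxes`, 8-connected components).
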