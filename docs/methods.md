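# Methods

## Problem

Cervical vertebral maturation (CVM) staging reads skeletal maturity from the
morphology of the C2–C4 vertebral bodies on a lateral cephalogram. Six
ordered stages CS1–CS6 bracket the mandibular growth peak: lower borders of
all three bodies start flat (CS1); a concavity appears on C2 (CS2), then C3
(CS3), then C4 (CS4); body proportions progress from horizontal-rectangular
(CS4) through square (CS5) to vertical-rectangular with deepened concavities
(CS6). The package implements both routes to a stage:

1. a **rule-based stager** operating on five landmarks per body
   (Clp, Cla, Cm, Cup, Cua), and
2. a **compact convolutional network** trained directly on (preprocessed)
   images.

Because clinical cephalograms are private, everything is exercised on a
synthetic generator whose geometry obeys the same morphology rules, with
ground-truth landmarks per image.

## Landmark measurements and decision cascade

Three measurements per body, all rotation-invariant (Euclidean segment
lengths, not axis projections):

- concavity depth `d`: perpendicular distance of Cm *below* the Clp–Cla
  chord, clamped at 0 (y grows downward);
- tapering ratio `|Cup−Clp| / |Cua−Cla|` (posterior/anterior height);
- lengthening ratio `|Clp−Cla| / |Cua−Cla|` (base/anterior height).

Thresholds (defaults, at 256-px image scale, rescaled linearly with image
size): a border is *concave* when `d ≥ 1 px`, *deepened* at `d ≥ 2 px`; a
body is *square* when the lengthening ratio lies in [0.95, 1.05] and
*vertical* below 0.95. The cascade tests the most mature stage first
(CS6 → CS1, first match wins), which resolves the overlap between the
qualitative stage descriptions: every finite feature triple maps to exactly
one stage.

## Synthetic generator

Each sample stacks a C2 lower-border wedge plus full C3 and C4 bodies,
centered, with per-stage parameter ranges (one editable table) for concavity
depths, the shared taper, and per-body lengthening ratios. Ranges are
validated at configuration time by staging every corner of each stage's
parameter box through the rule cascade — a malformed table is rejected, and
every in-range draw round-trips by construction. Concavity is rendered as a
quadratic dip of the lower border with maximum depth at Cm.

Rendering choices that matter:

- **Supersampling.** Bodies are rasterised at 4× resolution and box-averaged
  down. At the 64-px working scale the stage-defining concavities are
  sub-pixel (0.6–1.6 px); hard rasterisation erases them (CS2 becomes
  indistinguishable from CS1), while anti-aliasing preserves them as
  intensity gradation. `supersample=1` gives exactly quantised
  background/foreground/rim levels, used by tests that need discrete
  intensities.
- **Pose jitter** (rotation, scale) is applied to landmarks and silhouettes
  with the same affine map, so stored landmarks always describe the pixels.
- **Intensity model**: background 60, body fill 190, a ~1-px bright rim 235
  (cortical outline), optional random-direction linear shading plane,
  optional per-image exposure gain/offset, optional per-image polarity
  inversion (mixed display LUTs), then additive Gaussian noise, clipped to
  8 bits.

Two presets define the study conditions. *Easy*: noise σ=8, shading
amplitude 20, ±3° rotation, ±4 % scale. *Hard*: noise σ=25, shading 80,
gain ±40 %, offset ±40, polarity inversion with probability 0.5, ±6°/±8 %
pose jitter — an archive whose absolute gray levels are unreliable while
local structure is intact. What the generator does **not** emulate: soft
tissue and bone texture, overlapping anatomy, detector blur/scatter, true
anatomical shape variation. Passing benchmarks therefore demonstrate that
the pipeline's machinery works end to end, not clinical-grade accuracy.

## Preprocessing

Crop and resize follow standard practice (area-weighted downsampling to
avoid aliasing the thin rims). Sobel magnitude uses the classic unnormalised
3×3 kernels. The three local filters share a structuring element (square or
disk, reflected or zero-padded borders):

- local mean and median via `scipy.ndimage`;
- local entropy `H = −Σ pₙ ln pₙ` over the histogram of windowed
  intensities with a configurable bin count (natural log by default; base
  is an option). Implementation: the image is quantised to bin indices once,
  per-bin window counts come from box sums (square windows) or a footprint
  correlation (disks), and `H = ln n − (Σ c ln c)/n`. A naive per-pixel
  reimplementation serves as the test oracle (agreement to 1e−10).

Entropy responds to how many gray populations a window mixes, not to their
level — uniform histograms maximise it — so its output highlights structure
(edges, rims) and is largely invariant to smooth shading, exposure gain and
polarity. The benchmark preset uses a 7×7 square window with 8 bins: at the
hard preset's noise level, finer bins spread sensor noise across bins and
saturate the entropy map, while 8 coarse bins keep noise mostly within one
bin and reserve the response for real structure.

## Network and training

A "six-layer" structure: five blocks of
`conv 3×3 → batch-norm → ReLU → max-pool 2×2 → dropout` with filter counts
32-64-64-128-128, then `dense 1024 → batch-norm → ReLU → dropout → dense 6 →
softmax` (~0.8 M parameters at 64-px input). The dense width reads the
"32 × 32" fully-connected description as 1024 units. Implemented directly
in NumPy (NHWC, float32, im2col + GEMM convolutions, hand-written
backpropagation); training is deterministic given the seed on a fixed
platform.

Numerical/design choices:

- **Dropout rates** default to 0.1/0.1/0.15/0.2/0.25 (conv) and 0.4
  (dense). At 64-px input the late blocks see 2×2 and 1×1 maps; heavier
  rates (e.g. 0.3–0.5) inject so much multiplicative noise there that
  optimisation stalls on small datasets.
- **Dropout/batch-norm variance shift.** Running BN statistics accumulated
  under dropout overestimate inference-time variance; stacked five deep this
  collapsed evaluation-mode accuracy to chance. Before every evaluation the
  trainer re-estimates all BN statistics with dropout disabled
  (`refresh_batchnorm`, cumulative average over up to 512 training images).
- Loss is categorical cross-entropy, `−ΣΣ y ln ŷ`, probabilities clamped at
  1e−12 before the log; reported as a batch mean (a `sum` reduction is a
  config switch).
- Optimisers: SGD with momentum 0.9 or Adam (0.9, 0.999); default Adam at
  3e−3, in the basin the LR range test identifies on the benchmark.
- The LR range test raises the rate geometrically per batch,
  `lr_k = low·(high/low)^{k/(n−1)}`, records per-batch loss, restores the
  model afterwards; `select_lr` smooths the curve (moving average, window 5)
  and returns the rate at the steepest decrease, falling back to the lower
  bound with a warning when the loss never decreases.
- Self-training moves pool samples whose predicted class is correct *and*
  whose confidence reaches the threshold into the training set, logging
  every move.

## Evaluation

Confusion matrix (rows = true), classification report
(precision/recall/F1/support per class, overall accuracy; display rounding
is half-away-from-zero to 2 decimals, full precision retained), per-class
one-vs-rest accuracy `(TPⱼ+TNⱼ)/total` (the quantity summary tables report
per class — near 1.0 values are expected for a 6-class problem and must not
be confused with overall accuracy), and per-class 6×n probability-grid
rasters exportable as CSV/PNG.

## Benchmarks and problem sizes

- **Standard benchmark**: easy preset, 100 images/class at 64 px
  (60/20/20 split), default network, 30 epochs, batch 32. Mean test accuracy
  over seeds 1–3 is ≈ 0.93 (one CPU, ≈ 4 min per run).
- **Reduced comparative benchmark** (used where many runs are needed):
  30 images/class at 64 px, narrow 16-32-32-64-64 ladder with a 128-unit
  dense block, 10 epochs. Used for (a) the entropy-vs-raw comparison on the
  hard preset — entropy-filtered inputs beat raw inputs by ≈ 0.1–0.15
  accuracy because the filter cancels exposure/polarity nuisance — and
  (b) the depth check, where a sixth conv block (pool 1) scores below the
  five-block default, matching the observation that deeper does not help at
  this data scale. Images stay at 64 px in the reduced benchmark: coarser
  rasters lose the sub-pixel concavity signal outright.

## Known limitations

- The generator's inter-stage variability is a modelling choice; no
  published quantitative ranges exist.
- At 64 px, early-stage discrimination rides on anti-aliased sub-pixel
  intensity gradation; any preprocessing that quantises intensities (coarse
  entropy bins included) trades that signal for nuisance invariance. This is
  why entropy filtering helps only under the hard preset's gray-level
  corruption and is not enabled by default.
- Pure-NumPy training is single-threaded BLAS-bound; wall-clock scales
  roughly linearly in images × epochs (the sizes above were chosen for
  desk-scale runs).
- No automatic landmark detection on real radiographs; landmarks come from
  the generator or external files.
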