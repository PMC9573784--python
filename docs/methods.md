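# Methods

This document records the model, the algorithmic and numerical choices, and
the known limits of `carpelkit`. Units: lengths in mm, areas in mm², times in
days after the start of the observation window, temperatures in °C,
thermal time in degree days (°C·day).

## 1. Measurement model

A carpel image is a single carpel on a dark background, photographed with a
known scale (`mm_per_px`). Two traits are defined on binary masks:

* **Stigma area** — the area of the *envelope* covered by the stigma hairs
  (not the summed area of individual hairs): pixel count of the stigma mask
  × `mm_per_px`². No boundary smoothing is applied; the phenotype is defined
  directly on the annotation.
* **Ovary diameter** — the transverse width of the ovary, perpendicular to
  the carpel's long axis. Five steps: (1) centroid of the stigma mask,
  (2) centroid of the ovary mask, (3) the line through the ovary centroid
  perpendicular to the centroid–centroid axis, (4) the two points where that
  line exits the ovary mask, (5) their Euclidean distance × `mm_per_px`.

Degenerate inputs are flagged rather than guessed at: `empty_stigma` (no
stigma pixels), `fallback_axis` (stigma centroid missing or within 1 px of
the ovary centroid — the long axis is then the major principal axis of the
ovary's second moments), `off_edge` (the measurement chord reaches the image
border, so the diameter is a lower bound), `empty_ovary` (diameter undefined,
reported as NaN).

### Numerical choices

* Exit points are found by marching from the ovary centroid along both
  directions of the measurement line in **0.25-px steps** with
  nearest-pixel membership, keeping the membership run that contains the
  centroid. This is robust to ragged rasterised boundaries and concavities
  touching the chord; the step bounds the quantisation error of each
  endpoint by 0.125 px. On rasterised analytic ellipses (semi-axes
  40–110 px) the measured chord is within 2% of the closed form, within 1%
  for a radius-100 circle.
* Coordinates are (row, col) with origin at the top-left pixel centre; all
  geometry is done in float64.

## 2. Segmentation networks

Two independent networks annotate each image: a 1-channel **stigma network**
and a 2-channel **ovary network** (ovary + stigma outputs). Architecture:
U-Net-style encoder–decoder, depth 4, base 16 channels (so widths
16/32/64/128 with a 256-channel bottleneck), two 3×3 convolutions per block,
2×2 max pooling, nearest-neighbour ×2 upsampling with skip concatenation,
1×1 convolution + sigmoid head. Training: soft-Dice loss
`1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1 (averaged over batch items and
channels), Adam with learning rate 1e-3, ~15 epochs, 80/20 train/validation
split, dihedral-8 augmentation (the generator produces no preferred
left/right chirality, and up/down orientation is easy for the network to
re-learn). Images are bilinearly resized to the network input size
(default 128 or 256); predicted probability maps are resized back and
thresholded at 0.5 at native resolution, so all geometry uses each image's
own scale. Post-processing keeps the largest 8-connected component and
fills interior holes.

### Why pure numpy, and what that required

The package targets a CPU-only environment with no deep-learning framework,
so the network engine (`carpelkit.nn`) is hand-written numpy with explicit
backward passes. Choices that matter:

* **3×3 convolution as nine shifted GEMMs** (one per kernel tap) instead of
  im2col: identical arithmetic, ~9× less cached memory in the backward pass
  and ~1.7× faster on one CPU — this is what makes 15-epoch training of two
  networks fit in minutes.
* **Instance normalization** (per-sample, per-channel over H×W, learnable
  gain/shift) in every 3×3 block. This is load-bearing: without it the deep
  ReLU stack driven by Adam at lr 1e-3 blows up its activations within a few
  dozen steps (observed growth from ~1 to ~6×10⁴), the logits saturate, the
  Dice gradient vanishes and training collapses to all-background.
* **Gradient-norm clipping** (global norm 5) and a **logit clamp at ±25**
  before the sigmoid; both keep a transiently saturated network recoverable
  in float arithmetic.
* **Batch size 2.** The architecture, loss, optimizer, learning rate and
  epoch count are fixed by the measurement protocol; batch size is an
  implementation choice. With only ~50 training images and a fixed epoch
  count, smaller batches mean more Adam steps: batch 2 reaches ~0.88
  held-out DSC where batch 4 reaches ~0.78 at the same epoch budget.
* Float32 forward/backward with float64 Adam moments and loss; training is
  bit-reproducible for a given seed on a given machine.

On the synthetic benchmark (80 seeded 128×128 scenes, 60 train / 20 held
out, 15 epochs) the stigma network reaches mean post-processed held-out DSC
≈ 0.96 (worst image ≈ 0.87) and the ovary channel ≈ 0.99. These floors
(0.89 / 0.95) come from the measurement protocol this package implements;
the synthetic scenes are easier than real micrographs, which is why the
floors are treated as lower bounds, not as claims about field performance.

## 3. Validation

Dice similarity coefficient `DSC = 2|A∩B| / (|A|+|B|)`; two empty masks
score 1 by convention (both annotators agree the tissue is absent),
empty-vs-non-empty scores 0. Cross-validation groups images by
developmental stage (1 young / 2 fully developed / 3 deteriorated) ×
sampling method (fixed / non-fixed) and reports per-group means and
paired measurement differences. No hypothesis testing is performed.

## 4. Time-course analysis

* **Outlier filter**: per cultivar × timepoint group, drop values outside
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; quartiles use linear interpolation
  between order statistics (`numpy.quantile` default). Groups smaller than
  4 pass through (quartiles of 2–3 points are not meaningful).
* **Loess**: local quadratic regression with tricube weights over the
  span-fraction (default 0.9) nearest neighbours, evaluated on a 0.1-day
  grid. The pointwise 95% CI is `fit ± z·σ·‖l‖`, where `l` is the local
  fit's equivalent-kernel row and σ² is the residual variance of the
  smoother at the observed points (dof = n − 3). This is hand-rolled
  because the protocol requires a local *quadratic* with confidence
  intervals, which common lowess implementations (local linear, no CI) do
  not provide.
* **Degree days**: `Σ max(T̄ᵢ, 0)` over an inclusive day-index window
  (base 0 °C). For phase durations with fractional-day boundaries, the
  cumulative sum is linearly interpolated within the day.
* **Phases**: on the smoothed stigma curve relative to its maximum —
  growth ends at the first rise through 85%, the peak ends at the first
  drop through 85% after the maximum, a 40%-drop senescence marker is also
  reported, and deterioration runs to the last sampling point. Crossing
  times are refined by linear interpolation between grid points. Boundaries
  the curve never reaches are reported as censored, not extrapolated.
* **Ranking**: cultivars are ordered by deterioration onset (peak end)
  descending — latest onset = slowest developer; censored onsets rank
  slowest; ties break on the 40% marker, then the label. With exactly three
  cultivars the conventional slow/moderate/fast labels are attached.

Span-0.9 Loess is a heavy smoother: with five timepoints over 18 days it
biases sharp boundaries outwards by 1–2 days (visible in the README worked
example). The protocol accepts this bias in exchange for stability across
noisy field data; comparisons between cultivars smoothed the same way are
unaffected to first order.

## 5. Synthetic generators

All generators are pure functions of (parameters, seed) and bit-reproducible.

* **Scenes**: dark background, speckled green ellipse ovary, fan-shaped
  stigma envelope rising from the ovary apex rendered as a taper-radius
  polygon (±4% ripple) filled with a pale haze plus ~250–450 anti-aliased
  hair strokes, Gaussian pixel noise. The stigma ground truth is the
  envelope polygon — the quantity the phenotype defines — not the hairs.
  Deterioration shrinks the envelope linearly to 30% of its turgid size;
  fixation applies a further 0.85 linear shrink. Scene geometry is validated
  against the image bounds at construction.
  *Realism limits*: no occlusion, no debris, one carpel per image, no
  illumination gradients beyond a simple ovary shading term; real
  micrographs are harder, so segmentation scores here are optimistic.
* **Trajectories**: stigma area follows `A_max · logistic rise ·
  exponential decline` with the logistic centred `6/growth_rate` before the
  peak, so the rise is >99.7% complete at `t_peak`: the curve's maximum sits
  at `t_peak` and post-peak crossings follow the decline rate alone, which
  gives closed-form truth for the phase boundaries (root-found to 1e-10 for
  the recorded `true_boundaries`). Ovary diameter saturates as
  `D_max(1 − e^{−rt})`. Noise is mean-preserving lognormal
  (σ² = ln(1 + CV²)). Optional outlier contaminants are placed 3 IQR above
  the group's third quartile plus a quarter of the median, so they always
  clear the 1.5×IQR fence.
* **Temperature**: daily means = base + 60-day sinusoid + AR(1) noise with
  innovation scale 0.25 × amplitude (amplitude 0 ⇒ exactly constant);
  gap-free date index enforced.

## 6. Scope and limitations

* The networks here are trained on synthetic scenes; no claim is made about
  field images, cultivar-specific morphology, or transfer to other
  microscopes. Scale-bar detection is out of scope — `mm_per_px` must be
  supplied per image.
* Statistical comparisons between annotation sources (ANOVA-style testing)
  are out of scope; the validation report is descriptive.
* Phase boundaries are only as good as the smoother; with the default span
  they are biased outwards for sharply peaked cultivars (quantified above).
* The diameter algorithm assumes a convex-ish ovary near the measurement
  chord; strongly concave masks are handled by keeping the centroid's
  membership run, but the result is then the width of that run, not a
  maximal chord.
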