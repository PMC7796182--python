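# Methods

## Problem and pipeline

The task is two-fold: (a) classify a cropped leaf image as corn seedling
(+1) or weed (−1), and (b) localize and classify every plant in a field
scene. The pipeline is classical: hand-designed descriptors, PCA fusion,
an SVM, and color-space segmentation. All images are 8-bit RGB; leaf crops
are normalized to 256×256 by uniform scaling (factor `256 / max(H, W)`,
bilinear, anti-aliased when shrinking) with the remaining canvas set to
exact zeros, so leaf shape is never distorted. The scaled content is
anchored top-left by default (deterministic and round-trip friendly);
centered placement is available as an option.

## Descriptors

All descriptors consume the Rec. 601 grayscale of the normalized crop.

* **HOG** — 9 unsigned orientation bins over [0°, 180°), [−1, 0, 1]
  derivative kernels, cells of 64×64 px by default, 2×2-cell blocks with
  one-cell stride, L2-Hys normalization with a zero-block guard (a
  constant image gives an all-zero descriptor). Length
  `(256/cell − 1)² · 36`: 324 at cell 64, ranging from 36 (cell 128) to
  34,596 (cell 8).
* **Rotation-invariant LBP** — 8-bit codes over the exact 3×3
  neighborhood, clockwise from the top-left neighbor (MSB); a neighbor ≥
  center sets the bit, so flat regions deterministically give pattern 255.
  Two rotation-invariant reductions are exposed: the minimum over the 8
  circular bit-rotations (`rotlbp_code`; e.g. pattern 125 → 95), and the
  10-bin riu2 quantization used for the per-cell histograms (uniform
  patterns binned by set-bit count, all non-uniform patterns pooled).
  The riu2 choice makes the histogram length `(256/cell)² · 10` — 160 at
  cell 64 — while remaining rotation invariant; border pixels are
  excluded. Histograms are raw counts (the SVM standardizes per
  dimension).
* **Gabor** — 5 wavelengths in half-octave progression (4, 4√2, 8, 8√2,
  16 px), 8 orientations kπ/8, bandwidth 1 octave; complex kernels applied
  by FFT convolution over a reflect-padded frame (so homogeneous inputs
  give homogeneous responses); mean magnitude over a 3×3 grid of
  sub-blocks; 360 values ordered scale-major, then orientation, then
  row-major blocks.
* **GLCM** — gray values quantized to 64 levels; ordered pixel pairs at
  displacement (0, 1) (the horizontal 0° direction; 45°/90°/135°
  selectable) counted and normalized to sum to 1. Six statistics in fixed
  order: energy, contrast, correlation (0 under zero variance), sum
  entropy, entropy, inverse difference moment. Natural logarithms
  throughout; a texture-free matrix has entropy 0.
* **GGCM** — Sobel gradient magnitude (reflect boundary), max-normalized
  and quantized to 64 levels, jointly histogrammed with the 64-level gray
  plane per pixel. Fifteen statistics: small/large gradient dominance,
  gray/gradient non-uniformity, energy, gray/gradient mean, gray/gradient
  mean square error, correlation, gray/gradient/mixed entropy, inertia and
  inverse difference moment. The classical naming lists fourteen; the
  gradient mean square error completes the standard fifteen-statistic set
  and is ordered directly after its gray counterpart.
* **Hu moments** — eight invariants from normalized central moments
  η_pq (x = column, y = row) of the intensity distribution: the seven
  classical invariants plus
  `φ8 = 2η11[(η30+η12)² − (η03+η21)²] − 2(η20−η02)(η30+η12)(η21+η03)`,
  which vanishes for four-fold mirror-symmetric shapes. Classical η
  normalization is used.

Every statistic is cross-checked in the tests against an independent
double-loop implementation to 1e−10 on small toy images.

## Fusion, PCA and the classifier

A strategy string names descriptors in concatenation order
(case-insensitive, "+"-separated); the fused dimension is the sum of
member dimensions (all 24 supported combinations are enumerated in the
tests). PCA stores the training mean and an input-dim × p orthonormal
projection (sign fixed so each component's largest-magnitude loading is
positive); the identical transform is applied to training, validation and
field-region samples. Strategies of ≤ 15 input dimensions skip PCA by
default — reducing already-tiny statistic vectors only loses
information — and `"auto"` otherwise retains the smallest p explaining
99% of the variance. The 95% convention common elsewhere is too
aggressive here because the LBP count histograms concentrate most
variance in a few directions while class information also lives in the
tail. A retention search over explicit candidates
(`select_retention`, ties to the smallest p) mirrors the
highest-validation-accuracy selection protocol.

PCA is fitted on the full feature matrix before the train/validation
split, reproducing the published step order (reduce, then shuffle and
split); standardization, by contrast, is fitted on the training fold
only. The SVM is linear by default (the fused vectors are
high-dimensional and near-separable; RBF with C/γ is available), trained
on the stratified 70% with seeded shuffling, and scored on the held-out
30% by `(TP+TN)/total`. The repeated-experiment helper reruns the split
and fit over a seed list (default 0..9) and reports per-run and mean
accuracy; feature extraction is shared across runs.

## Field detection

Scenes are converted to CIE L\*a\*b\* (sRGB, D65). K-means with k = 2
(k-means++, 10 restarts, fixed seed; fitted on a 50k-pixel subsample for
large scenes, then applied to all pixels) clusters the *a* channel; the
cluster with the lower mean *a* is vegetation. If the two means are
closer than 8 *a*-units (pure-soil scenes), the detector warns and
returns no vegetation. Components are 8-connected; regions smaller than
0.1% of the scene (configurable) are dropped. Each region is cropped by
its bounding box with non-component pixels zeroed, then passed through
the same tight-crop → zero-padded normalization path as a training leaf,
so the train and field feature distributions match by construction.

## Synthetic data generator

The generator emulates the study conditions: ~1000 leaf crops per class
for training/validation, and 1024×600 field scenes containing 2–3 corn
seedlings and 3–4+ weeds.

Leaves are parametric blade unions: corn renders 1–3 broad, gently curved
blades (length ≈ 0.88, half-width ≈ 0.24 of the half-frame) with smooth
low-frequency shading plus regular parallel vein striping (period ≈ 9
canonical px); weeds render ~5 thin blades (half-width ≈ 0.075) carrying
band-limited high-frequency speckle. Hues are green (Lab *a* ≈ −30);
backgrounds are exact zeros. All texture is defined in canonical 256-px
coordinates, so a plant rendered at any size carries the same texture
statistics after normalization; each leaf crop is rendered at a random
native size (160–256 px), tightly cropped and normalized, emulating
variably sized real crops. Scenes are brown soil (Lab *a* > 0) with
smooth multiplicative noise and darker elliptical clods; plants are
placed without overlap (bounded retries, `TooCrowdedError` on failure)
and the truth records class, tight box, area, per-plant seed and the
exact vegetation mask.

`texture_contrast` ∈ [0, 1] linearly interpolates every class-dependent
parameter toward the pooled mean: at 1 the classes are fully distinct; at
0 the class distributions coincide and any classifier must fall to
chance — the built-in negative control.

What the generator does **not** emulate: photo-realistic leaf venation
and serration, illumination changes (sunny/cloudy), occlusion and plant
overlap, edge-truncated plants, soil debris with vegetation-like color.
Passing tests therefore demonstrate that the pipeline recovers the
texture/shape contrasts it was designed to measure, not field-ready
accuracy on real imagery.

## Numerical and protocol choices

* Entropies use natural log; correlations are defined as 0 when either
  marginal variance vanishes; all statistics are finite on constant
  images.
* LBP ties (neighbor = center) set the bit — deterministic on flat
  regions.
* Gray quantization is `value * levels // 256`; gradient quantization is
  max-normalized before binning (a constant image puts all mass at
  gradient level 0).
* Split seeds, k-means seeds and generator seeds are explicit arguments
  everywhere; equal seeds give bit-identical splits, masks, scenes and
  result tables.
* Problem sizes used by the heavier checks: 1000+1000 leaves for the
  end-to-end training check, 20 scenes with 2 corn + 4 weeds each for
  detection, 300+300 leaves for the negative control — comfortably
  estimating the binary accuracies involved while keeping the suite quick
  to run.

## Known limitations

* The k-means foreground rule assumes vegetation is the greener (lower
  *a*) cluster; scenes dominated by green non-vegetation would fool it.
* Touching plants merge into one region; no overlap resolution is
  attempted, and plants clipped by the frame edge are classified from
  whatever fraction is visible.
* The saved "p×p coefficient matrix" description in the source protocol
  cannot map an input-dim vector to p dimensions when they differ; the
  bundle stores the standard input-dim × p projection plus the mean.
* Timing/throughput of training and prediction is hardware-dependent and
  out of scope.
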