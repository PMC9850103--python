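# Methods

This note documents the models and procedures behind `wellpred`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish about real microscopy data.

## Microwell growth simulator (`wellsim`)

**Model.** Growth is a stochastic cellular automaton on the pixel lattice of
the rendered image, restricted to a circular well mask (radius 11 px in a
24×24 frame, standing in for a 30 µm well at ≈1.3 µm/px). Each occupied
pixel is a clonal patch of one strain: green (T6SS-positive) or red
(T6SS-negative). One step comprises

1. *Synchronous division*: every occupied pixel divides with its strain's
   probability (`p_div_G`, `p_div_R`) into a uniformly chosen empty
   4-neighbor inside the well; simultaneous proposals for one target are
   resolved in random order (first proposer wins).
2. *Contact killing*: every red pixel with g ≥ 1 green 4-neighbors is
   emptied with probability 1 − (1 − `p_kill`)^g. Killing is
   one-directional (green kills red) and leaves no rendered corpse, since
   fluorescence images show live signal only.

A lattice automaton with 4-neighborhood division is the simplest scheme
that reproduces compact colony morphology and well saturation; no
continuum or single-cell mechanical model is attempted.

**Rendering.** Occupied pixels fluoresce in their strain's channel with
intensity 0.6 + 0.4 × (3×3 occupancy density), so colony interiors are
brighter than edges. Frames get a Gaussian point-spread blur
(`blur_sigma` = 0.5 px) and additive clipped Gaussian background noise
(`noise_sigma` = 0.02). With blur and noise disabled, a rendered pixel is
exactly pure green or pure red at intensity ≥ 0.6, which is what makes the
population-curve round-trip test exact.

**Defaults and calibration.** Videos are 14 frames of 24×24 px at 30-min
cadence, 4 automaton steps per frame. The common seeding regime places 3
green and 2 red single-pixel colonies uniformly at random; the rare regime
(probability `rare_pattern_fraction` = 0.1, "uncommon" not being quantified
further) places 3× as many, producing many small colonies of both strains.
Division and killing probabilities (`p_div_G` = 0.30, `p_div_R` = 0.55,
`p_kill` = 0.05) were calibrated by simulation so that (a) the median first
frame with ≥95 % in-well occupancy is 8, matching saturation "around frame
8" in the emulated corpus, and (b) the red strain robustly ends with more
pixels than the green one (≈220 vs ≈160 on average), reflecting the growth
cost of carrying the T6SS machinery. The red–green asymmetry comes from
the division-rate gap; contact killing partially offsets it by clearing
space around green colonies, which is why `p_kill` is kept small. Initial
colony counts are phenomenological: no inoculum data exists for the
emulated wells.

**What the simulator does not emulate.** Photobleaching, focus drift,
illumination gradients, strain-specific autofluorescence, cell morphology
below pixel scale, and mutual (green↔red) dueling. Tests passing on this
corpus show the pipeline's plumbing and learning dynamics are sound, not
that the predictor would reach any particular accuracy on real microscopy.

## Preprocessing chain (`preprocess`)

Order is fixed as truncate → RGB→HSV → center crop → temporal
interpolation → resize → (test withholding) → augmentation → split.

* **Truncation** keeps frames 1–7 of 14; later frames are static after
  saturation and add no dynamics worth learning.
* **HSV conversion** separates species (hue), concentration (saturation)
  and presence (value); the standard hexcone transform is used and
  round-trips with its inverse to 1e-6.
* **Recentering** crops a 24×24 window centered on the centroid of
  suprathreshold pixels of the time-averaged brightness (V channel), with
  the threshold chosen by the triangle (Zack) construction on a 256-bin
  histogram: the threshold bin maximizes perpendicular distance to the
  line from the histogram peak to the farthest nonzero tail. With no
  suprathreshold pixel the geometric center is used and a warning logged.
* **Temporal interpolation** is per-pixel linear, 7 → 20 frames over
  [0, T−1], endpoints exact.
* **Resize** is bilinear, 24×24 → 32×32, with the half-pixel-center
  coordinate convention (output pixel *i* samples input coordinate
  (i + 0.5)·scale − 0.5). Stated explicitly because resize dialects
  differ by a half-pixel shift.
* **Augmentation** samples (source, transform-composition) pairs without
  replacement per source — compositions of up to 2 distinct transforms from
  {hflip, vflip, rot90/180/270, blur σ=0.5 px, noise σ=0.01} — dealt
  round-robin over sources until the corpus reaches `target_corpus_size`
  (default 392 from 43 eligible sources). A target-size parameter is used
  because no fixed transform multiplicity maps 43 to 392 exactly.
  Augmentation happens after HSV conversion, channels treated
  independently; every applied transform is recorded in the copy's lineage.
* **Splitting.** Test sequences (default 5 of 48) are withheld *before*
  augmentation and never serve as augmentation sources. The 80/20
  train/validation split has two modes: `clip` (random over individual
  sequences, which can leak near-duplicate augmented copies across the
  split) and the default `lineage` (whole source lineages on one side).
  Both are provided because the leaky clip-level split is the common
  practice this pipeline mirrors, while lineage splitting is the
  defensible default.

## Predictor (`model`, `nn`)

**Architecture.** A stack (default 4 layers) of spatiotemporal LSTM cells
with dual memories: per-layer temporal memory `c` across time, and a
spatial memory `m` that ascends the layer stack within a timestep and
returns from the top layer to the bottom layer of the next timestep (gate
equations in the README). A plain convolutional LSTM (`cell_type=
"conv_gated"`) is available as a fallback; zeroing the spatial-memory
pathway of the dual cell reduces it exactly to the fallback, which is
tested. Default hidden width 32 and learning rate 3e-4 are the selected
operating point; layer count 4, kernel 5 and patch 4 follow the standard
configuration of this architecture family. Frames are space-to-depth
folded (patch 4) before the recurrence.

**Training.** Adam (β₁ = 0.9, β₂ = 0.999) on the MSE between predicted and
observed frames over the prediction window (input 10 frames, horizon 10),
HSV channels weighted equally. The network output is linear during
training (clipping to [0, 1] only when frames are materialized, so
gradients are not cut); gradients flow through the autoregressive
feedback. Forget-gate biases start at +1 so memories persist early in
training. Scheduled sampling is off by default (a flag enables a linearly
decaying ground-truth feed). Every evaluation interval the validation MSE
and a perceptual score (on a capped subset of validation sequences, for
cost) are recorded and the best-validation parameters checkpointed.
"Epochs" at full scale are interpreted as gradient iterations
(`max_iterations`, default 50 000); all shipped tests and scripts run
desk-scale models (≤1 000 iterations, hidden ≤ 8, one CPU) — the problem
sizes used are stated with each result.

**Implementation.** The network runs on a small reverse-mode autodiff
engine over numpy arrays (im2col convolutions, iterative topological-sort
backward). It exists because the model *is* the package's core and needs
nothing beyond a dozen primitive operations; gradients are verified
against central differences to ~1e-11 and the cell against a per-pixel
evaluation of the gate formulas (tolerance 1e-5, in practice ~1e-15).
Float64 throughout; determinism is exact given `rng_seed`.

**Toy benchmark.** `make_growing_disk_corpus` generates deterministic
videos of a soft-edged green disk growing linearly in radius (random
center, initial radius 1–2.5 px, rate 0.15–0.35 px/frame, 16×16, 20
frames). Any predictor that learns the growth law must beat the
persistence baseline (repeat the last observed frame), whose error is the
area swept between frame 10 and frame t. A 2-layer, 8-channel model
trained 300 iterations beats persistence ~5× and shows monotone
error accumulation with horizon after smoothing (window 5).

## Metrics (`metrics`)

* **MSE** is reported on the 0–255 pixel scale by default (the magnitude
  regime in which video-prediction errors are conventionally quoted), with
  a unit-scale option.
* **Perceptual distance**: the default backend is 1 − SSIM averaged over
  channels — self-contained, symmetric, zero for identical frames. LPIPS
  is a pretrained network and therefore an optional plugin behind the same
  interface; requesting it without a local installation raises rather than
  silently substituting, because the two scores are not numerically
  comparable.
* **Population curves** classify a pixel as green if hue ∈ [90°, 150°],
  red if hue ∈ [330°, 30°] (wrapping 0°), both requiring V ≥ 0.1 and
  S ≥ 0.1. Bands are configurable and validated against overlap; whether
  dim pixels should count at all is exposed as thresholds, not asserted.
* **Colony tables** label connected components of each strain's classified
  mask per frame (default 8-connectivity, `min_size` 1 — a "colony" has no
  agreed operational definition, so the loosest one is the default) and
  record size and centroid. Sizes per strain per frame sum exactly to that
  strain's population count under the same thresholds.

## Pipeline (`pipeline`, `cli`)

One YAML config with nested `sim` / `preprocess` / `predictor` / `metrics`
sections mirroring each module's defaults; unknown keys and type
mismatches are rejected naming the offending key. Per-stage seeds are
spawned from the global seed via `SeedSequence`, logged, and recorded with
SHA-256 hashes of the corpus manifests in `run_manifest.json`; identical
seeds reproduce identical simulate/preprocess outputs bit-for-bit.
Training determinism is exact on one CPU in this implementation. Stage
failures abort with the stage name; partial outputs are preserved.

## Known limitations

* The simulator's phenomenological calibration targets two corpus-level
  statistics (saturation frame, strain asymmetry); it was not fitted to
  real image data and its colony morphologies are lattice-angular.
* The numpy predictor is CPU-bound and desk-scale; full-scale training
  (hidden 32, 50 000 iterations, 392 videos of 32×32) is supported by the
  same code path but is not exercised in the shipped tests.
* Hue-band population counts saturate once colonies overlap after blur;
  they are a proxy for abundance, not a calibrated cell count.
* The perceptual default (structural dissimilarity) is not LPIPS; scores
  from the two backends must not be compared across studies.
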