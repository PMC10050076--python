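# Methods

`blurmap` estimates the lateral diffusion coefficient *D* of single
molecules directly from their motion-blurred camera images, and maps *D*
at super-resolution by spatially binning localized molecules. This note
documents the forward model, the regressor, the mapping procedure, the
numerical choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not show.

## Forward model

A molecule diffusing at *D* (µm²/s) during a camera exposure *T* (default
9 ms) traces a 2-D Brownian path; its image is that path convolved with
the microscope point spread function (PSF), sampled at the photon level
and pixelized. The simulator resolves the path into `n_micro_steps`
(default 1000) micro-steps of interval *t = T / n*. Two stepping schemes
are provided:

* **fixed** (default): every micro-step has length √(4·D·t) in a
  uniformly random direction;
* **gaussian**: per-axis Normal(0, √(2·D·t)) increments.

Both give MSD(τ) = 4·D·τ exactly in expectation; the fixed-length scheme
is the default because at n = 1000 micro-steps the two are
indistinguishable at the image level while the fixed scheme makes the
per-step contract (`|Δx| = √(4Dt)`) exactly testable. Trajectory
arithmetic runs in float32 (steps ~10 nm, positions ~µm, so single
precision keeps sub-0.01 nm accuracy at ~6× the speed).

**Rendering.** The expected photon budget is `photon_rate × T`
(photon rates 60–120 photons/ms, i.e. 540–1080 expected photons per
molecule, matching typical experimental single-molecule counts of
500–1200). Photons are apportioned uniformly over the micro-step
positions with Poisson-realized totals; each photon is displaced by a
draw from an isotropic Gaussian PSF (σ = 110 nm ≈ 0.21·λ/NA for 600 nm
emission at NA 1.45 — a stand-in for a bead-measured profile, and
config-exposed) and binned onto the 160 nm pixel grid. The 7×7 ROI is
centered on the camera pixel containing the photon centroid, mirroring
downstream centroid localization and preserving sub-pixel phases.
Per-pixel background is Poisson(b) + Normal(0, σ_b), defaults b = 10
counts, σ_b = 3, chosen as EMCCD-plausible and config-exposed; pixel
values are floored at 0.

**Diffusivity fields.** `DiffusivityField` supports uniform fields,
single square/circular inclusions, multi-inclusion patterns and labeled
rasters. In a field, the local *D* at the current position sets each
micro-step length, so molecules straddling a boundary genuinely mix
mobilities. `render_frame_sequence` composes whole frames at a Poisson
molecule count per frame (default density 0.1 molecules/µm²/frame,
SMLM-typical) with per-frame ground truth.

## The regressor

A single blurred image does not determine *D* — the same *D* yields
diverse trajectories — so the input unit is a stack of `n_ch = 40`
mutually uncorrelated 7×7 images at a common *D*, stacked along the
channel axis. The network is a shallow residual CNN: conv(3×3) →
batchnorm → Swish blocks (widths 32-32-64-64, identity shortcuts where
widths match), global average pooling, and a dense regression head
(~77k parameters; kept small to avoid overfitting simulated data).
Swish replaces ReLU for smoother regression behaviour. It is
implemented as a compact numpy framework (im2col convolution on BLAS,
float32 by default, float64 available for the finite-difference
gradient tests that guard the backward passes).

**Training.** MSE loss on the physical *D* scale against labels on a
0–6 µm²/s grid, SGD with momentum 0.9 (conventional; the momentum value
is config-exposed), batch 128, initial lr 0.003 divided by 10 every 25
epochs, 60 epochs — these full-scale defaults generate 121 labels ×
100 stacks × 20 brightness/background combinations = 242,000 stacks.
Inputs are normalized per image by median subtraction (removing the
local background pedestal) and a fixed global count scale of 100 stored
in the checkpoint. A stratified 10% per-label holdout provides the
reported validation metrics; no schedule decisions are made on it.
Training aborts with a diagnostic if the loss goes non-finite.

**Domain randomization.** Brightness and background vary widely in
experiments, so training data are augmented over a 4 × 5 grid of photon
rates (60–120 photons/ms) and background means (2–18 counts). Whether
one stack should hold a single combination or mix them is an open design
choice; `build_training_dataset` supports both. The benchmark recipe
mixes combinations **per image**, because the application assembles
stacks from spatial-bin pools in which molecules of different brightness
coexist; a model trained on homogeneous stacks systematically
underestimated *D* by ~12% on such mixed stacks.

**Reduced-scale recipe.** The benchmark recipe
(`train_scaled_model`) uses 25 labels (0.25 µm²/s spacing), the full
20-combination randomization grid, 20 stacks per (label, combo)
(10,000 stacks) and 25 epochs (lr ÷10 every 10). It reaches a held-out
single-stack σ(%Error) of ~11–19% over *D* = 1–4 µm²/s, versus ~12%
for the full-scale recipe; the full-scale defaults remain available
unchanged.

## Localization

Frames are processed independently (no trajectory linking — the central
premise is that every single-frame image is an observation). Detection:
Gaussian smoothing (σ = 1 px), threshold at median + 6 robust-σ
(1.4826·MAD) of the smoothed frame, local maxima with a minimum
separation. Localization: per-ROI background is the median of the ROI
border pixels; the background-subtracted (floored) intensity-weighted
centroid is reported in nm at the pixel-center convention, and the ROI
is re-cropped about the nearest integer pixel. Overlap rule: any two
ROIs in a frame that share a pixel discard **both** molecules (the rule
is symmetric, so filtering is order-independent); edge-truncated ROIs
are likewise discarded.

## Mapping

Retained localizations are binned on a fixed grid (default 120 nm,
half-open cells `[k·g, (k+1)·g)`, boundary records to the higher index).
A bin with pool size p is evaluated only if p > 10. Evaluation draws
m = 100 stacks of n_ch images from the pool — without replacement when
p ≥ n_ch, otherwise from a virtual pool holding each image j times with
j the minimum integer satisfying j·p > n_ch, so no image repeats more
than j times — and averages the m model outputs; negative averages are
clamped to 0 for physical relevance. Per-bin RNG streams derive from
(seed, i, j), making maps independent of bin evaluation order and
reproducible. The arithmetic mean of the m outputs is the default
combiner (a median option exists).

## Benchmarks and their protocols

* **Held-out precision**: 400 fresh stacks per *D* ∈ {1,2,3,4};
  %Error = (E − T)/T × 100; T = 0 is excluded from %Error (absolute
  error is reported for the 0 label). Evaluation pools draw
  per-molecule photon rates uniformly from 60–120 photons/ms at the
  default background — the brightness spread a bin pool exhibits.
* **Precision vs image budget**: 400 independent pools of p_i images at
  D = 3 ensemble-evaluated per budget p_i ∈ {40, 80, 160}; compared
  against the step-distance MLE at the same budget. The MLE closed form
  D̂ = Σr²/(4Nτ) (Rayleigh step-length likelihood) has relative SE
  1/√N and each step consumes two images (non-overlapping pairing,
  N = ⌊p/2⌋; overlapping pairing would correlate steps and break the
  1/√N law). The analytic law is verified by Monte-Carlo inside the
  benchmark. The MLE baseline draws ideal Rayleigh steps — motion blur
  and localization error are deliberately not added, as the comparison
  line is the analytic trend.
* **Pattern replica**: ~1 µm square and circular inclusions at
  4 µm²/s in a 2 µm²/s background over a 3.84 × 1.92 µm domain sized to
  tile a 120 nm grid (32 × 16 bins); 200 molecules per bin on average,
  positions taken from photon centroids. Transition width across a
  boundary is the number of bins strictly between the last bin within
  10% of the left plateau and the first within 10% of the right
  plateau, with plateau levels estimated from the profile itself
  (median of bins 2–6 bins away from the crossing); this isolates
  spatial sharpness from any global offset, which the bin-wise error
  distribution scores separately. Bins geometrically intersected by the
  true boundary are flagged and excluded from the interior error
  statistic, since they have no single ground-truth value.

For budget reasons the replica produces localized molecule images
directly from the field (trajectory → rendered ROI → photon-centroid
position) rather than through whole-frame rendering and detection; the
full TIFF-movie → detect → localize → map path is exercised end-to-end
at smaller scale in the tests and examples.

## What the synthetic benchmarks do not show

The simulator emulates 2-D diffusion in the focal plane with an
isotropic Gaussian PSF, ideal photon statistics and spatially uniform
background. It does not model out-of-focus blur (3-D diffusion),
anomalous or confined diffusion, within-frame photophysics
(blinking/bleaching), EM-gain excess noise, or a measured asymmetric
PSF — so passing benchmarks demonstrate the method's statistical
machinery, not robustness to those experimental effects. A measured PSF
kernel can be substituted via the config when available.

## Reproducibility

Every randomized stage takes a `numpy` Generator or an integer seed; a
single root seed fans out into named sub-streams (simulate / train /
map) via SHA-256, and dataset cells use counter-derived streams so
content is independent of generation order. Checkpoints are single-file
`.npz` archives holding weights, architecture config, normalization
constants and batchnorm statistics; save → load → predict is
bit-identical. Artifact-producing runs write a JSON manifest with the
configs in effect and SHA-256 digests of the outputs.
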