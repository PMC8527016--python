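# Methods

## The problem

Laser-induced breakdown spectroscopy (LIBS) fires a pulsed laser at a
seed; the resulting micro-plasma emits atomic lines whose positions
identify elements (Ca, K, Mg, Na, C, H, O, N, Si, Fe, plus the CN
molecular band) and whose intensities reflect elemental content.
Seed varieties differ in elemental composition, so a classifier over
LIBS spectra can identify variety without DNA assays. The study
design this package reproduces acquires **three spectra per seed**
(three ablation points), for K = 10 varieties × 200 seeds, on a
230–904 nm grid, and asks for a per-seed variety decision.

## Pipeline

1. **Crop** to 242–882 nm (the grid edges carry detector noise).
   Bounds are inclusive.
2. **Area normalization** (per spectrum): `X_i = x_i / Σ_i x_i`,
   removing shot-to-shot intensity scale.
3. **Variance mask**: wavelengths whose standard deviation over the
   *calibration* spectra is below `rel_threshold × max_j std_j`
   (default `rel_threshold = 1e-6`) are dropped everywhere.
   Exactly-constant columns are always dropped. Fitting on
   calibration only avoids information leakage into held-out sets.
4. **Split by seed**, stratified per variety, at ratio 3:1:1 into
   calibration / validation / prediction. All three spectra of a
   seed share its partition (asserted on every split). Non-divisible
   counts use largest-remainder rounding with ties favouring
   calibration.
5. **Spectral matrix**: each seed's three normalized spectra are
   stacked into a 3×P matrix, rows ordered by ablation-point index.
   This is the single-channel "image" the 2D networks consume.

## Classifiers

The residual network family (1D on single spectra, 2D on spectral
matrices) is: stem Conv(64 ch, k7, p3, s2) + BN + ReLU → MaxPool(k3,
s2, p1) → four residual blocks with channels 64, 64, 128, 128 (k3,
p1, s1) → global average pool → dense → softmax over K classes.
Each block computes

    y = ReLU( BN₂(Conv₂(ReLU(BN₁(Conv₁(x))))) + W·s(x) )

where `s` is the identity, or a 1×1 projection at the 64→128
channel change, and **W is the propagation coefficient**:

* **fixed** — W ≡ 1 (plain ResNet);
* **per-block adaptive** — W₁..W₄ independent trainable scalars
  ("PCA-ResNet");
* **shared adaptive** — a single trainable W* used by all blocks and
  updated synchronously, so W₁=W₂=W₃=W₄=W* after every step
  ("PCSA-ResNet"). Implemented as one parameter object referenced by
  all four blocks; its gradient accumulates over blocks, which is
  exactly the synchronous update.

All W initialize at 1.0, so adaptive modes start as a plain ResNet.
On 2D inputs the 3-row axis is convolved like the wavelength axis;
any strided stage switches the row-axis stride to 1 once that axis
has size ≤ 2, so the stem maps rows 3 → 2 and the blocks keep 2.

Seed-level decisions: the 2D network classifies the matrix directly;
1D models classify the three spectra and take a **majority vote**
(≥ 2 agreeing labels win; an all-distinct tie goes to the argmax of
the summed probability vectors, a residual exact tie to the lowest
class index). Baselines are Euclidean KNN (k ∈ 3..20 by validation
accuracy, ties to the smallest k) and an RBF SVM (C, γ on integer
powers of ten in 1e-8..1e8, five-fold stratified CV on calibration,
one-vs-one).

### The numpy layer engine

The networks run on a compact channel-last layer engine written with
numpy (`libsid.nn`): im2col convolutions (one GEMM per layer),
batch normalization, ReLU, max/global-average pooling, a dense head,
and hand-derived backward passes for every layer, verified against
central finite differences in float64. Two numerical choices matter:

* **Batch-norm running statistics are bias-corrected** exponential
  averages (momentum 0.1, accumulator divided by `1-(1-m)^t`). The
  conventional zero/unit initialization needs hundreds of batches to
  wash out; at this package's data scales (area-normalized
  intensities ~1e-3, short trainings) that left evaluation-mode
  statistics orders of magnitude off while training-mode learning
  looked healthy. Bias correction makes the running statistics
  unbiased from the first batch.
* **float32 by default** for training throughput; `NetworkSpec.dtype`
  accepts float64, which the gradient-verification tests use so that
  finite-difference quotients are not dominated by rounding.

## Training

Plain SGD (no momentum or weight decay), categorical cross-entropy,
staged learning rates: each stage (rate, validation threshold) runs
epochs until whole-validation accuracy reaches the threshold or a
per-stage epoch cap. Rates must strictly decrease and thresholds
must not decrease; the published four-stage schedule is rates
0.25/0.124/0.05/0.01 with thresholds 0.84/0.86/0.88/0.887. "One
epoch" is a full pass over the calibration set; the threshold check
uses evaluation-mode batch-norm statistics at epoch end. Returned
weights are those at stopping time (no best-so-far selection).
Batch size defaults to 64.

## The synthetic-data generator

The study's raw spectra are not deposited, so the simulator stands
in. A spectrum is

    shot · ( baseline(λ) + Σ_j m_vj · b_j · Lorentz(λ; λ_j, w_j) ) + ε

* **Lines**: the 21 element lines named above at their NIST
  wavelengths, unit-height Lorentzians of half-width 0.3 nm (CN band
  1.5 nm), with plausible relative base intensities `b_j` (resonance
  Ca/K/Na/H lines strong). LIBS lines are pressure-broadened, so a
  Lorentzian is the natural localized positive shape; the pipeline
  is insensitive to the exact profile.
* **Variety profiles**: per-variety line multipliers `m_vj`,
  log-normal around 1 with log-sd `separation` (default 0.25 ≈ 25 %
  compositional spread — enough structure that all pipeline stages
  have signal to find, without making classes overlap-free by
  construction at high noise).
* **Shot fluctuation**: one LogNormal(0, 0.10) factor per *seed*
  (the three spectra come from one physical seed; this correlates a
  seed's spectra, which is what makes majority voting meaningful).
  Area normalization removes it exactly, by design.
* **Baseline**: a random cubic in [0, `baseline_amplitude`]
  (default 0.05) per spectrum — a smooth continuum that survives
  normalization as nuisance variation; never explicitly corrected.
* **Noise**: additive Gaussian, sd 0.01 (≈1 % of a unit line
  height) per grid point; spectra are clipped at 0.
* **Grid**: default step 0.05 nm over 230–904 nm (~13.5k points;
  the instrument's 0.01 nm would give 67k — configurable but
  desk-unfriendly).

The instrument's real noise statistics are unpublished; these
defaults are declared placeholders exposed in `SimConfig`, not
calibrated values. What the simulator does **not** emulate: plasma
physics (Saha–Boltzmann temperatures, self-absorption),
matrix effects, wavelength drift, or correlated detector noise.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers variety structure of this idealized
form — not that the published real-data accuracies are reproduced,
which is impossible without the data.

## Scaled-down study sizes

Tests and the acceptance script run a reduced design chosen once for
desk-scale runtimes: 10 varieties × 30 seeds × 3 spectra on a 0.5 nm
grid (≈1.3k kept variables after crop and mask), split 18/6/6 seeds
per variety. The 2D network then trains on 180 matrices, so the
scaled study uses batch size 16 and a two-stage schedule
(0.25 → 0.05, thresholds 0.90/0.95) with a moderate per-stage epoch
cap — at batch 64 an epoch is only three gradient steps and the
model undertrains before the caps. The full published design
(200 seeds, four stages, batch 64) remains the default configuration.

## Interpretation

* **Saliency**: the gradient of the selected class's output with
  respect to every input pixel, the selection made by a one-hot
  "correct" vector. Default differentiates the softmax probability
  (the dense head is described by its ten probability values); a
  `logit` option differentiates the pre-softmax score, the common
  practice because probability gradients saturate for confident
  predictions. Raw signed gradients are returned;
  `display_map` gives the absolute, min-max-scaled version for
  plotting.
* **Layer features**: stem max-pool and last-block feature maps are
  channel-averaged then flattened; the dense layer contributes its
  raw score vector (softmaxing those rows reproduces the network's
  predictions exactly).
* **t-SNE**: perplexity 30 on a PCA pre-reduction — 12 dimensions
  for the convolutional layers, 6 for the dense layer (which has
  only K = 10 features). Requires ≥ 3 × perplexity samples.
* **PCA**: mean-centred covariance eigendecomposition (centring is
  implied by "covariance" even where the projection algebra omits
  it); explained variance λ_k/Σλ; eigenvector signs fixed by making
  each component's largest-magnitude loading positive.

## Known limitations

* The engine is CPU/numpy; it is deliberately minimal (no momentum
  optimizers, no GPU, no data augmentation) and sized for the
  desk-scale synthetic studies above.
* With the default simulator the classes are fairly separable;
  published real-data accuracy gaps between model variants (≤ 2
  percentage points) are far inside the simulator's run-to-run
  variance and cannot be meaningfully compared here.
* Checkpoints store weights and batch-norm running statistics but
  not the averaging state, so resuming training restarts the
  running-statistics accumulators.
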