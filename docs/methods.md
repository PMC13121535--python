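# Methods

## Problem

Prostate-zone segmentation models trained at one institution degrade at
another (different scanners, protocols, intensity distributions), and
naively fine-tuning on the new institution erases what was learned at the
first — catastrophic forgetting.  This package implements a hybrid
transformer–CNN segmentation network together with a synchronous
continual-learning scheme (elastic weight consolidation and a
stability-augmented variant) and evaluates the whole loop on synthetic
two-institution phantoms small enough to train on a single CPU core.

## Network

Input is a 2-D grayscale slice on the 0–255 scale (divided by 255
internally).  Stages, in order:

1. **Transformer encoder.**  Non-overlapping p×p patches, row-major, are
   flattened and linearly embedded to D dimensions; a learnable positional
   matrix is added.  Each block applies multi-head scaled dot-product
   self-attention and a GELU MLP, both with residual connections and
   *post*-norm layer normalization — `Z' = Norm(Z + MSA(Z))`,
   `Z'' = Norm(Z' + MLP(Z'))` — i.e. normalization after the residual sum,
   matching the governing equations rather than the more common pre-norm
   arrangement.  Blocks can attend globally or inside k×k token windows
   (additive mask); the default is global for all blocks.  A neck
   (linear projection + layer norm) maps tokens to `neck_dim` channels and
   reshapes them to a √N×√N spatial map.
2. **Bridge.**  Every block's token map X⁽ˡ⁾ enters a skip chain
   `S⁽ˡ⁾ = F_skip(X⁽ˡ⁾) + S⁽ˡ⁻¹⁾` (1×1 convolution transforms; the
   level-0 previous term is zero).  The chain uses the *aggregated*
   previous output S⁽ˡ⁻¹⁾; a `raw_chain` flag switches to the raw X⁽ˡ⁻¹⁾
   reading.  Aggregation is `S_nested = Σ wᵢ S⁽ⁱ⁾` with unconstrained
   trainable scalars initialized to 1/n_levels (no softmax — nothing in
   the formulation requires the weights to be a partition of unity).
   Fusion with the neck map T is `F_fusion = W_f S_nested + W_t T`
   (1×1 convolutions).
3. **CNN decoder.**  log2(p) blocks of (concatenate skip → 1×1 projection
   → 3×3 conv + GELU → ×2 upsampling) restore full resolution.  The
   skip source is S_nested, bilinearly resampled to each block's
   resolution.  Upsampling is `hybrid` by default: fixed bilinear ×2
   followed by a learnable stride-1 3×3 refinement initialized to the
   identity — this keeps the ×2 geometry unambiguous and checkerboard-free
   while retaining a learnable transposed-convolution-like component.
   Pure `bilinear` and true `transposed` (zero-dilation + learnable conv)
   modes are available.
4. **Final fusion.**  The transformer map is progressively windowed
   (per-level channel transforms W_i shared across overlapping 4×4 blocks
   with 50 % overlap; since the shared transform acts per pixel, the
   coverage-normalized overlap-add reduces to the pointwise transform —
   the windows structure the parameterization, not the arithmetic), then
   bilinearly upsampled to image resolution.  The decoder output is
   calibrated into the transformer channel space (1×1 projection, then
   depthwise 3×3 + GELU).  A per-location two-logit softmax over the
   concatenated features yields the relevance R ∈ [0,1] of the transformer
   source; `F_scaled = R·F_T + (1−R)·F_C`; a second two-logit softmax on
   F_scaled yields α+β=1 and `F_fused = α F_T + β F_C`.  A 1×1 head
   produces 3 class logits; predicted labels are the per-pixel argmax with
   ties broken toward the lowest class index.

Both softmaxes are read as *two logits per location* (transformer vs CNN
source); this makes "R ∈ [0,1]" and "α + β = 1" literal identities.
Fusion happens at full image resolution, with F_T taken *post*-windowing.

### Scales

* `ModelConfig.desk()` — p=8, D=64, 2 blocks, 4 heads, neck 16, decoder
  channels (32, 16, 8), 64×64 slices (~144 k parameters).  Default for
  single-run tests.
* `ModelConfig.micro()` — D=32, 2 heads, neck 12, 32×32 slices (~32 k
  parameters).  Used by the multi-seed benchmark so that five seeds ×
  three modes finish in a few minutes on one core.
* `ModelConfig.paper_scale()` — a ViT-B-like configuration provided for
  completeness; it is not trainable at desk scale.

No pretrained encoder checkpoint ships with the package.  When one is
supplied, `load_pretrained_encoder` blends it at initialization time,
`θ' = λ θ_pre + (1−λ) θ_train` with λ = 1 by default (the blend ratio is a
free parameter); re-blending per epoch is deliberately not done.  The
freeze policy marks attention blocks and neck frozen; the optimizer skips
them entirely, so they are bitwise unchanged by training.

## Continual learning

After Task-1 training the model stores, per trainable parameter:

* the anchor θᵒˡᵈ (the selected best weights);
* the empirical Fisher score `Fᵢ ≈ (1/N) Σₙ (∂ log P(yₙ|xₙ,θ)/∂θᵢ)²`,
  with log P the per-pixel log-softmax probability of the *observed* class
  summed over pixels (empirical Fisher at the observed labels, matching
  the estimator's (xₙ, yₙ) form; labels are not re-sampled from the
  model);
* the stability `S(θᵢ) = (1/T) Σₜ |θᵢ,ₜ − θᵢ,ₜ₋₁|`, accumulated at every
  optimizer step of Task 1 (T = total steps).

Fine-tuning minimizes the task loss plus

* EWC: `(λ/2) Σ Fᵢ (θᵢ − θᵢᵒˡᵈ)²`, default λ = 100;
* vEWC: `λ Σ (Fᵢ + S(θᵢ)) (θᵢ − θᵢᵒˡᵈ)²`, default λ = 50.  The governing
  equations print both a λ/2 and a λ form of this penalty; the λ·I form is
  the default and a `halved_vewc` flag selects the other.  With the flag
  set and S ≡ 0 it reduces exactly to EWC.

The printed Task-2 update carries a "+γ∇R" term; descent on the penalized
objective L_new + γR implies a minus, and the implementation descends on
the penalized loss.  After Task 2 the Fisher state is refreshed by
re-estimation on Task-2 data and accumulated as a sample-count-weighted
running average with the prior scores.  Frozen parameters carry no
importance state — they cannot drift.

At desk scale the stability values (mean per-step movement, ~1e-4) are
orders of magnitude below typical Fisher scores, so vEWC behaves almost
identically to EWC here; its distinct behaviour would emerge with larger
λ-free importance or longer noisier training trajectories.

## Phantom data

Each case is an ellipsoid "prostate" near the grid centre: the inner
ellipsoid (axes scaled by `tz_fraction` = 0.6) is TZ (label 1), the rim PZ
(label 2), the rest background.  Intensity = per-class mean × bias field +
Gaussian noise, where the bias field is 1 + amplitude·(random low-order
polynomial over normalized coordinates) — a smooth scanner-shading
surrogate.  Per-case seeds are `config.seed + case index`, so a dataset is
a pure function of its config.  Default native grid 20×320×320 exercises
the adaptive-crop path; `benchmark_config` uses 10×96×96 for the training
benchmarks.

Institution styles (free parameters; the real cohorts give no quantitative
inter-institution intensity statistics):

| style | bg | TZ | PZ | noise σ | bias |
|---|---|---|---|---|---|
| A | 45 | 105 | 185 | 6 | 0.10 |
| B | 95 | 175 | 120 | 10 | 0.20 |

A resembles a bright-PZ T2-weighted protocol.  B is brighter, noisier and
has the TZ/PZ contrast ordering *reversed* — a deliberately adversarial
shift chosen so that, at desk scale, zone identity genuinely depends on the
learned institution-specific intensity mapping and naive fine-tuning
measurably damages Task-1 performance.  What the phantoms do **not**
emulate: anatomical shape variability, lesions, partial-volume texture,
multi-parametric channels, inter-rater label noise.  Passing benchmarks
therefore demonstrate the mechanics of the architecture and of
consolidation-based retention, not clinical-grade accuracy.

## Preprocessing

Adaptive centre crop removes `floor(dim/r)` voxels per in-plane side
(default r = 4; the exact crop-window rule is a documented choice — the
formulation fixes only that the coordinates derive from dividing width and
height by a predefined ratio).  Images are resampled with (tri)linear
interpolation and labels with nearest-neighbour on the same pixel-centre
aligned grid, preserving the class set {0, 1, 2}.  Intensities are
per-volume min-max normalized to [0, 255]; a constant volume maps to
zeros.  Volumes are sliced along depth for 2-D training.  Augmentation
appends one randomly chosen lossless transform per slice (horizontal /
vertical flip or right-angle rotation), doubling the sample count;
fine-tuning uses flips only ("conservative") to respect small sample
sizes.  Right-angle rotations are a choice — lossless transforms keep
masks exact.

## Training

Loss = Dice + MSE: `1 − soft Dice` averaged over the two foreground
classes with smoothing ε = 1 in numerator and denominator (an empty zone
predicted empty is perfect; background is excluded because the zones are
the targets), plus the mean squared error between softmax probabilities
and the one-hot target.  Both weights default to 1.  Adam, lr 1e-3, batch
8, global-norm gradient clipping at 1.0; the learning rate halves after 10
epochs without validation-loss improvement; early stopping after 25; the
checkpoint keeps the epoch with the best validation Dice.  Few-shot
fine-tuning: 15 samples, 10 epochs, early stopping, conservative
augmentation, default lr 1e-5.

All arithmetic is float64 numpy; runs are exactly reproducible given the
seed.  Mixed precision is not used.

## Benchmark and evaluation

The two-institution benchmark (per seed): generate A (7 cases: 3 train /
1 val / 3 test) and B (4 cases: 2 fine-tune pool / 2 test) at 10×96×96,
preprocess to 10×32×32, keep prostate-bearing slices, train the micro
model 30 epochs on A, then fine-tune on 15 B-slices for 10 epochs under
each mode.  The benchmark fine-tunes at lr 1e-3: with a ~32 k-parameter
model and ~40 optimizer steps, the production-scale "very low" rate would
leave the weights essentially untouched and the comparison empty; the
rate is scaled so that unconstrained fine-tuning visibly adapts (task-2
Dice ≈ 0.84) and forgetting can actually occur.  Reported quantities:

* **retention** = mean task-1 test DSC under the fine-tuned weights /
  the same mean under the task-1 weights (1 at task 1 by construction;
  the forgetting-curve quantity is this ratio, a documented definition —
  absolute-DSC curves can be emitted as well);
* **silhouette** of per-(slice, zone) fused-feature mean vectors on
  task-1 test slices, computed directly from s(i) = (b−a)/max(a,b) with
  Euclidean distances and singleton clusters scoring 0 (on raw pooled
  features, not a 2-D projection — this removes a stochastic embedding
  step from the comparison);
* per-zone DSC, mIoU and symmetric mean surface distance on re-stacked
  3-D volumes.  Surfaces are face-connected boundary voxels
  (6-neighbourhood in 3-D, 4 in 2-D); distances default to voxel units
  and scale by the spacing when given; an empty surface yields NaN (the
  "failed to segment" flag).  Worst-case DSC is the minimum over cases.

## Numerical choices

* Post-norm block ordering exactly as written; layer normalization over
  the embedding dimension (the normalization operator is otherwise
  unspecified).
* Argmax ties → lowest class index (determinism).
* DSC/mIoU both-empty convention → 1.
* Min-max normalization of a constant volume → 0.
* Penalized updates are plain descent on L_task + penalty; the EWC
  quadratic is strictly convex for positive importance, so λ→∞ pins
  parameters to the anchor (verified to 1e-2 at λ = 1e6).
* The autodiff engine implements only the operations the network uses;
  convolution is im2col + BLAS matmul; bilinear resizing is a pair of
  fixed interpolation matrices (exact adjoint for free).

## Limitations

* 2-D slice-wise segmentation only; no 3-D context.
* The phantom domain shift is intensity-driven; geometric domain shift is
  not modelled.
* vEWC is distinguishable from EWC only when stability terms are
  comparable to Fisher scores, which these short smooth runs do not
  produce.
* The desk/micro scales are orders of magnitude below a ViT-B; absolute
  Dice values on phantoms do not transfer to clinical data.
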