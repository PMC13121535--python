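# zoneseg

Hybrid transformer–CNN segmentation of prostate zones (transition zone TZ,
peripheral zone PZ) with **synchronous continual learning**: after training
on one institution's scans, the network is fine-tuned on a second
institution with an elastic-weight-consolidation penalty so that it adapts
without catastrophically forgetting what it learned first.  Everything runs
at desk scale on synthetic two-institution phantom MRI, so the whole
pipeline — data, training, continual fine-tuning, evaluation — is
reproducible on one CPU core in minutes.

## Who this is for

Researchers studying cross-institution robustness of medical-image
segmentation models who want a small, fully inspectable reference
implementation of:

* a ViT-style patch-token encoder with post-norm blocks
  `Z' = Norm(Z + MSA(Z))`, `Z'' = Norm(Z' + MLP(Z'))`, a neck projection to
  spatial maps, and a pretrained-weight blend
  `θ' = λ θ_pre + (1−λ) θ_train` with an encoder freeze policy;
* a bridge stage with nested skip connections
  `S⁽ˡ⁾ = F_skip(X⁽ˡ⁾) + S⁽ˡ⁻¹⁾`, learnable aggregation
  `S_nested = Σᵢ wᵢ S⁽ⁱ⁾`, and fusion `F_fusion = W_f S_nested + W_t T`;
* a U-Net-style CNN decoder (3×3 conv + GELU bridge layers, ×2 progressive
  upsampling);
* a final fusion head with per-location relevance
  `R(x,y) = softmax(W_R [F_T | F_C] + b_R)`, adaptive scaling
  `F_scaled = R·F_T + (1−R)·F_C`, and attention-guided mixing
  `F_fused = α F_T + β F_C`, `(α, β) = softmax(W_A F_scaled + b_A)`;
* continual learning by **EWC**,
  `L = L_task + (λ/2) Σᵢ Fᵢ (θᵢ − θᵢᵒˡᵈ)²` with the empirical Fisher
  `Fᵢ ≈ (1/N) Σₙ (∂ log P(yₙ|xₙ,θ)/∂θᵢ)²`, and **vEWC**, which adds a
  stability term `S(θᵢ) = (1/T) Σₜ |θᵢ,ₜ − θᵢ,ₜ₋₁|` to form the importance
  `I(θᵢ) = Fᵢ + S(θᵢ)`;
* evaluation by per-zone DSC `2|P∩G|/(|P|+|G|)`, mIoU, symmetric mean
  surface distance, retention curves, and TZ/PZ feature-space silhouette
  scores `s(i) = (b(i) − a(i)) / max{a(i), b(i)}`.

Because no deep-learning framework is assumed, the network and its
training run on a compact numpy reverse-mode autodiff engine included in
the package (`zoneseg._autograd`, `zoneseg._nn`).

## Worked example

```python
import numpy as np
from zoneseg import phantom, preprocess
from zoneseg.model import ModelConfig, ZoneSegNet
from zoneseg.training import TrainConfig, train_task, mean_foreground_dice

# two-institution phantoms: ellipsoidal prostate, inner TZ, PZ rim
cfg = phantom.PhantomConfig(grid_shape=(12, 128, 128),
                            prostate_axes=(4.0, 26.0, 26.0),
                            tz_fraction=0.6, seed=1)
cases = phantom.generate_institution_dataset(cfg, 4)
pairs = preprocess.preprocess_dataset(
    cases, preprocess.PreprocessConfig(crop_ratio=4.0,
                                       target_shape=(12, 64, 64)))
fg = [p for p in pairs if (p.mask > 0).any()]
train = [p for p in fg if p.case_id < 2][:16]
val   = [p for p in fg if p.case_id == 2][:6]
test  = [p for p in fg if p.case_id == 3]

model = ZoneSegNet(ModelConfig.desk(64, seed=0))
ck = train_task(model, train, val, TrainConfig(epochs=30, lr=1e-3, seed=0))
print(round(ck.history["train_loss"][0], 3),
      round(ck.history["train_loss"][-1], 3))
print(round(mean_foreground_dice(ck.build_model(), test), 3))
```

prints (30 epochs, ~40 s on one CPU core):

```
1.004 0.058
0.961
```

i.e. the combined Dice+MSE training loss falls from 1.004 to 0.058 and the
model segments held-out phantom slices at a mean foreground Dice of 0.96.

The continual-learning experiment is one call:

```python
from zoneseg.benchmark import BenchmarkConfig, run_benchmark
df = run_benchmark(BenchmarkConfig(seeds=(1, 2, 3, 4, 5)))
print(df.groupby("mode")[["retention", "silhouette"]].mean().round(3))
```

```
      retention  silhouette
mode
ewc       0.996       0.687
none      0.397       0.573
vewc      0.996       0.687
```

Naive fine-tuning on institution B keeps only ~40 % of the institution-A
Dice; EWC/vEWC keep ~99 %, and the TZ/PZ clusters in feature space stay
better separated (higher silhouette) — the qualitative signature of
knowledge retention.

A CLI mirrors the library (`zoneseg simulate / preprocess / train /
finetune / evaluate / retention / benchmark`).

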