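# duoseg

Dual-decoder contextual-attention segmentation for 2-D medical images
(dynamic speech/cardiac MRI slices and similar grayscale data), implemented
from the ground up in numpy — including its own reverse-mode autodiff
engine — so that every block of the architecture is verifiable on one CPU
without a GPU framework, downloads or external data.

## The model

A hierarchical pyramid vision transformer encoder (overlapping convolutional
patch embedding, spatial-reduction self-attention, convolutional
feed-forward) maps a 3×H×W image to a feature pyramid x₁..x₄ at strides
4/8/16/32. Two decoder branches consume it:

* **High-level context branch.** x₂..x₄ are fused to a stride-8 map
  y = Conv₁ₓ₁([Conv₃ₓ₃(x₂), Upconv(x₃), Upconv(Upconv(x₄))]); a single
  residual U-block (two max-pool levels, a dilation-2 bridge, skip-merging
  decoder, residual add) extracts a multi-receptive-field context map C;
  each deep feature is then gated in residual form

      x′ᵢ = xᵢ ⊙ softmax_channels(projᵢ(C)) + xᵢ ,

  and the enhanced pyramid is fused by progressive 1×1 up-convolutions into
  full-resolution class logits P₁.

* **Low-level guided branch.** x′₃ and x′₄ are aggregated to a stride-4
  guide h; an additive attention gate
  att(h, l) = l ⊙ σ(BN(Conv(σ(BN(Convₕ(h) + BN(Convₗ(l)))))))
  suppresses irrelevant regions of the detail-rich x₁; the gated feature is
  merged with h, refined by CBAM (channel attention → spatial attention →
  conv block) and mapped to logits P₂.

Training supervises both branches and their product with channel-wise
BCE + soft-Dice (equal weights):

    loss = L(σ(P₁), T) + L(σ(P₂), T) + L(σ(P₁)·σ(P₂), T)

At inference the branch probabilities are summed, S = σ(P₁) + σ(P₂), and
the label map is argmax over channels — no post-processing.

The package also provides a deterministic synthetic phantom generator
(cardiac disk/ring/crescent motifs and articulator-like bands), PNG/NIfTI
dataset I/O, Dice and (95th-percentile) Hausdorff evaluation, analytic
parameter/MAC accounting, and a Gaussian-noise robustness protocol.

## Worked example

```python
import numpy as np
from duoseg.phantoms import PhantomSpec, generate_phantom
from duoseg.pipeline import TrainConfig, evaluate, train

spec = PhantomSpec(size=64, n_classes=3, seed=17)
samples = [(s.image, s.labels) for s in (generate_phantom(spec, i) for i in range(8))]
config = TrainConfig(encoder_variant="tiny", num_classes=4, image_size=64,
                     max_steps=60, batch_size=8, seed=17, val_interval=60)
result = train(config, samples, val_samples=samples[:2])
print(result.log["total"].iloc[[0, 29, 59]].round(3).tolist())
_, summary = evaluate(result.model, samples, config)
print(round(summary["mean_dice"].iloc[0], 3))
```

prints (exactly, given the fixed seed)

```
[7.445, 2.66, 2.025]
0.244
```

— the joint loss falling from 7.45 to 2.03 over 60 desk-scale steps, and a
mean foreground Dice of 0.244 on the training phantoms (60 cheap steps are
a smoke run; the 300-step overfit protocol below reaches Dice ≈ 0.91).
The scripts in `examples/` walk through each capability: phantom
generation, capacity summaries, training and segmentation, metric
conventions, and the noise-robustness sweep. A thin CLI mirrors the
pipeline (`duoseg synth|train|predict|evaluate|summary`).

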