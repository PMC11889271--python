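# mrpunet

Dermoscopic skin-lesion segmentation with a multiscale-input-fusion,
residual-attention, pyramid-dilated-convolution U-Net (MRP-UNet), for
researchers building automated lesion-analysis pipelines and for anyone who
needs a fully seeded, download-free test bed for segmentation tooling.

Accurate delineation of a lesion from surrounding skin is the first step of
computer-aided melanoma diagnosis, and it is hard for well-known reasons:
lesions vary enormously in size, their borders are irregular and blurred,
their colour is non-uniform and often barely distinct from skin, and the
images are occluded by hairs, vessels, air bubbles and device frames. This
package implements a U-Net variant that attacks those failure modes with
three architectural pieces:

* **MIF — multiscale input fusion.** An image pyramid of the input (at full
  size: 576 → 288 → 144 → 72) is injected into the matching encoder levels by
  a 1×1 convolution plus residual addition, so every scale of lesion is seen
  at native resolution.
* **Res2-SE encoder blocks.** Each encoder stage replaces the classic double
  3×3 convolution with a Res2Net split-group block — channels are split into
  *n* groups with Y₁ = X₁, Y₂ = K₂(X₂), Yᵢ = Kᵢ(Xᵢ + Yᵢ₋₁) — followed by
  squeeze-and-excitation channel attention, dropout, batch normalisation and
  ReLU.
* **PDC bottleneck.** Between encoder and decoder, a cascade of 3×3
  convolutions at dilation rates (1, 2, 4, 8) whose intermediate outputs form
  pyramid branches (receptive fields 3, 7, 15, 31), concatenated and fused by
  a 1×1 convolution with a residual skip.

Evaluation uses the five standard pixel-overlap measures — accuracy,
sensitivity, specificity, Jaccard index JI = TP/(TP+FN+FP) and Dice
DC = 2TP/(2TP+FN+FP) — with both per-image-mean and pooled aggregation.

The network and its training loop run on a compact numpy compute backend
shipped inside the package (`mrpunet.nn`): reverse-mode autodiff with
hand-written, finite-difference-verified backward passes for convolution,
transposed convolution, batch norm, pooling and the rest. Everything runs on
a single CPU; a seeded synthetic dermoscopy generator stands in for the
public datasets so the full pipeline is testable offline.

## Worked example

```python
import numpy as np
from mrpunet import MRPUNetSegmenter
from mrpunet.synthetic import LesionParams, generate_lesion_image

samples = [generate_lesion_image(LesionParams(image_size=96, seed=s))
           for s in range(60)]
X = [s.image for s in samples]   # HxWx3 uint8 dermoscopy-like images
y = [s.mask for s in samples]    # aligned binary lesion masks

est = MRPUNetSegmenter(input_size=96, max_epochs=20, random_state=0)
est.fit(X[:48], y[:48])
print("parameters:", est.n_parameters_)
print("best val dice:", round(max(est.history_.val_dice), 4))
print("held-out dice:", round(est.score(X[48:], y[48:]), 4))
```

Output from this exact snippet (a few minutes on one CPU):

```
parameters: 916400
best val dice: 0.8999
held-out dice: 0.9239
```

916 400 is the trainable-parameter count of the 96-pixel "tiny" preset
(widths 8/16/32/64, bottleneck 128). The Dice values are overlap scores in
[0, 1] between predicted and true lesion masks — ≈ 0.92 means the predicted
lesions overlap the truth closely on the twelve images the model never saw,
after twenty epochs on forty-eight images.

The same workflow is available from the shell:

```bash
mrpunet generate --n 80 --seed 7 --out data/
mrpunet train --data data/ --out run/ --seed 1   # tiny preset by default;
                                                 # override via --config YAML
mrpunet eval --checkpoint run/best.ckpt --data data/ --out eval.csv
mrpunet predict --checkpoint run/best.ckpt --out preds/ data/syn0000.png
mrpunet ablate --data data/ --out ablation.csv   # ten-row module lattice
```

The ablation lattice covers all ten switch combinations, from the plain
U-Net baseline (`unet`) through single additions (`unet+mif`,
`unet+res2net`, `unet+se`, `unet+res2se`, `unet+pdc`) and pairs to the full
model (`mrp-unet`).

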