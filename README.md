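# imcsr

Instant multicolor super-resolution: separating several biological
structures that share one fluorescent channel from a *single*
superimposed grayscale SR image, with a residual channel-attention
CNN.

## Why

Multicolor SR live-cell imaging pays for every extra color channel in
acquisition time, photobleaching/phototoxicity and resolution (longer
wavelengths resolve worse). If the structures of interest —
e.g. microtubules (curvilinear), endoplasmic reticulum (reticular) and
lysosomes (punctate) — are labeled with the *same* fluorophore, one
fast single-channel acquisition captures them all at the best
wavelength, simultaneously. The price is a separation problem: the
recorded image x is the pixelwise superposition of the per-structure
images y_c, and recovering the y_c is an underdetermined,
morphology-driven inverse problem. `imcsr` solves it with a trained
CNN and ships everything needed to exercise the pipeline end to end on
synthetic phantoms — no microscope data required.

## What is in the box

| module | role |
| --- | --- |
| `imcsr.phantoms` | synthetic single-structure SR images (filaments / reticulum / puncta), imaging noise model, time-lapse drift |
| `imcsr.datapipe` | patch augmentation, superimposed training-pair construction (exact summation identity), temporal-continuity samples |
| `imcsr.network` | the separation CNN: conv-GELU stem, residual groups of residual channel-attention blocks, sigmoid output head |
| `imcsr.autograd` | the numpy reverse-mode autodiff engine and Adam optimizer the network runs on |
| `imcsr.objective` | combination loss λ·MSE + μ·(1−SSIM) and the α-weighted summation-consistency regularizer |
| `imcsr.trainer` | mini-batch training, validation by NRMSE, plateau learning-rate halving, best-checkpoint selection |
| `imcsr.evalmetrics` | percentile normalization → least-squares linear transform → NRMSE / global SSIM / PCC; Tukey box summaries |
| `imcsr.interface` | TIFF stack I/O, static and temporal-continuity inference, RGB composites |
| `imcsr.cli` | `imcsr simulate / build-dataset / train / separate / evaluate` |

The model is trained on pairs manufactured from single-structure
images: patches are augmented (crop, flips, 90° rotations), one patch
per class is summed into the input, and input plus targets share one
normalization scale so `input == Σ_c target_c` holds exactly. A
single model can emit all channels jointly, in which case the loss

    L = λ·MSE(ŷ, y) + μ·(1−SSIM(ŷ, y))
        + α·[λ·MSE(Σ_c ŷ_c, x) + μ·(1−SSIM(Σ_c ŷ_c, x))]

(λ=1, μ=0.1, α=0.02) additionally supervises the channel sum with the
input, suppressing cross-channel false positives. For time-lapse data
the network can take three consecutive superimposed frames and
separate the middle one ("temporal continuity"), which stabilizes
output along the time axis.

Evaluation follows a fixed chain: percentile-normalize prediction and
ground truth (10th/99th percentiles), fit an ordinary least-squares
affine map from the normalized prediction onto the normalized ground
truth, then report NRMSE, global SSIM and Pearson correlation. The
chain is exactly invariant to affine rescaling of the raw prediction.

## Worked example

Train a tiny two-class separator on synthetic phantoms and evaluate a
held-out pair (≈6 minutes on one CPU):

```python
import numpy as np
from imcsr import phantoms as ph, datapipe as dp
from imcsr.network import ModelConfig, build_model
from imcsr.trainer import TrainConfig, split_train_val, train
from imcsr.objective import LossWeights
from imcsr.evalmetrics import evaluate

# single-structure sources -> imaging noise -> 64x64 patches -> pairs
sources = {"puncta": [], "filament": []}
for i in range(4):
    p = ph.make_puncta((192, 192), n_spots=22, radius=2.0, seed=100 + i)
    f = ph.make_filaments((192, 192), n_filaments=7, width=2.0, seed=200 + i)
    sources["puncta"].append(ph.apply_imaging(p, snr="high", seed=300 + i))
    sources["filament"].append(ph.apply_imaging(f, snr="high", seed=400 + i))
patch_sets = {k: [q for img in v for q in dp.augment_patches(img, 30, 64, seed=j)]
              for j, (k, v) in enumerate(sources.items())}
pairs = dp.build_dataset(patch_sets, 240, seed=1)

model = build_model(ModelConfig(n_groups=2, n_blocks=2, n_features=16,
                                reduction=4, in_channels=1, out_channels=2), seed=1)
config = TrainConfig(strategy="all", initial_lr=1e-3, batch_size=3,
                     max_iterations=2000, val_fraction=0.1, val_interval=200, seed=1)
best, history = train(model, pairs, config, LossWeights())

_, val = split_train_val(pairs, 0.1, seed=1)
report = evaluate(best(val[0].input_array().astype(np.float32)).data,
                  val[0].target, channel_names=("puncta", "filament"))
print(report.to_frame().round(3))
```

Output of this exact script:

```
    channel  nrmse   ssim    pcc
0    puncta  0.120  0.875  0.843
1  filament  0.042  0.985  0.980
2      mean  0.081  0.930  0.912
```

Reading: after
normalization and the affine fit, the separated filament channel
deviates from its ground truth by an RMS of 0.042 normalized intensity
units with correlation 0.98; the harder punctate channel reaches 0.84.
SSIM near 1 indicates the global luminance/contrast/structure
statistics match. Training the same configuration with `alpha=0`
(no summation regularizer) leaves per-channel quality similar but
degrades the consistency between the channel sum and the input —
the effect the regularizer exists for.

The same pipeline is available from the shell:

```bash
imcsr simulate --structure puncta --shape 192 192 --n 22 --snr high --seed 1 --out puncta.tif
imcsr simulate --structure filament --shape 192 192 --n 7 --snr high --seed 2 --out filament.tif
imcsr build-dataset --inputs puncta.tif --inputs filament.tif \
      --classes puncta,filament --n-pairs 240 --patch-size 64 --seed 1 --out data/
imcsr train --config run.yaml --data data/ --out run/
imcsr separate --model run/model.npz --input mixture.tif --composite --out separated.tif
imcsr evaluate --pred separated.tif --gt gt.tif --out report.csv
```

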