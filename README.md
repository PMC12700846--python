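# glcsa

Pseudo-3D **g**lobal–**l**ocal **c**hannel/**s**patial **a**ttention for
U-Net zonal segmentation of prostate MRI (transition zone / peripheral zone),
implemented in pure NumPy on a small built-in reverse-mode autodiff engine —
no GPU or deep-learning framework required.

The attention block sits between a U-Net encoder and decoder. Skip features
from the first *n* stages are pooled into a shared token space (multiscale
embedding), refined by four attention maps — global channel (`Ygc`, c×c
similarity), global spatial (`Ygs`, token×token similarity), local channel
(`Ylc`, ECA-style sigmoid gating) and local spatial (`Yls`, dilated-convolution
gating) — plus a slice-interaction step that attends across the batch axis
(repurposed as pseudo-depth, so a 2D network shares information across
slices), and finally fused with the untouched tokens through a learned convex
combination before being upsampled back to each stage's resolution.

## Layout

| module | contents |
| --- | --- |
| `glcsa.nn` | minimal autodiff engine: tensors, conv2d, pooling, resize, layers, Adam |
| `glcsa.attention` | all attention submodules, fusion and the assembled block |
| `glcsa.networks` | vanilla U-Net, attention-bridge attachment, parameter accounting, checkpoints |
| `glcsa.data_io` | NIfTI/DICOM volumes, preprocessing (crop → resample → 0–255), augmentation, metrics CSV |
| `glcsa.synthetic` | prostate-like phantom generator + random tensor fixtures |
| `glcsa.train_eval` | multiclass Dice loss, DSC/IoU/MSD, training loop, Wilcoxon comparison |
| `glcsa.cli` | `glcsa synth / train / eval / compare` commands, YAML config schema |

## CLI

```bash
# generate a phantom dataset
glcsa synth --out data/phantoms --n 30 --seed 7 --noise 8.0

# train from a YAML config
glcsa train config.yaml             # or: --ablate no_glsa, --ablate la2, ...

# evaluate a checkpoint and compare two runs
glcsa eval --ckpt runs/a/checkpoint.npz --data data/phantoms --out runs/a/metrics.csv
glcsa compare runs/a/metrics.csv runs/b/metrics.csv --metric dsc
```

Minimal config:

```yaml
seed: 7
out_dir: runs/demo
data:
  synth: {n: 30, shape: [8, 64, 64], split: [0.5, 0.5], noise_sigma: 8.0}
network: {stages: 3, base_channels: 16}
glcsa: {ps: 4, glca_heads: 1, glsa_heads: 4}   # omit the section for a plain U-Net
train: {epochs: 40, lr: 0.0003, include_background: false}
```

Every architectural knob (patch size, head counts, attention order,
sequential/sum/parallel module fusion, patch vs global embedding, LA1/LA2
local mode, slice interaction on/off) is a field of the `glcsa:` section or a
named `--ablate` switch.

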