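# leafseg

Per-pixel segmentation of leaf damage — disease lesions, insect feeding
marks, miner tunnels — built around a *representation-first* architecture:
a frozen patch-feature encoder (a stand-in for a large self-supervised
foundation backbone) is adapted to dense prediction with a lightweight
Spatial Prior Module, concatenation fusion, a 1×1 Projection Module and a
Unet decoder ("DinoUnet"). The package is aimed at researchers in
agricultural image analysis who want a fully seeded, CPU-runnable testbed
for frozen-backbone adaptation: it ships a synthetic leaf/lesion generator
with exact ground truth, the combined cross-entropy + focal training
objective, a complete metric suite including per-lesion boundary RMSE, an
embedding-distance interpretability analysis, and a plain Unet baseline
for comparison.

## The model

For an input image `x` (side lengths divisible by 16):

    f_enc(x)  ∈ R^{H/16×W/16×C}        frozen patch encoder (patch 16)
    f_spm(x)  ∈ R^{H/16×W/16×C_spm}    MaxPool ∘ 4 ConvBlocks, intermediates
                                        at strides 2/4/8 kept as decoder skips
    f_fuse(x) = [f_enc(x), f_spm(x)]    channel concatenation (lossless)
    f_proj(x) = ReLU(Norm(Conv1×1(f_fuse(x)))) ∈ R^{H/16×W/16×C_target}
    M         = softmax(D_Unet(f_proj(x)))      per-pixel class probabilities

trained with `L = L_CE + L_focal`, where
`L_focal = −Σ_c α_c (1−p̂_c)^γ y_c log p̂_c` (defaults α=1, γ=2).
Only the spatial prior, projection and decoder receive gradients; the
encoder is frozen and its outputs are bitwise reproducible.

Evaluation reports Dice, IoU, pixel accuracy, precision/recall/F1 (micro
and macro), and per-lesion geometry RMSE (equivalent diameter
`√(4·area/π)` and marching-squares circumference) with missed lesions
penalised by their full measurement. The interpretability analysis pools
encoder features per sample, clusters them (k-means), and Pearson-
correlates each sample's distance to its cluster center with its
segmentation IoU.

There is no deep-learning framework dependency: the package includes a
small numpy reverse-mode autodiff engine whose gradients are verified
against finite differences in the test suite.

## Worked example

```python
import dataclasses
from leafseg import (simple_scene, RunConfig, ModelConfig, compare_models)

scene = simple_scene(size=64, seed=42)          # one leaf, white background
base = RunConfig(scene=scene, n_images=200, image_size=64,
                 model=ModelConfig(n_classes=4, seed=0), epochs=30)
runs = {"dinounet": dataclasses.replace(base, model_kind="dinounet"),
        "unet": dataclasses.replace(base, model_kind="unet")}
table = compare_models(runs, out_dir="runs/compare")
print(table[["model", "test_iou", "test_dice"]].to_string(index=False))
```

Output (one CPU, ~10 min):

```
   model  test_iou  test_dice
dinounet  0.884521   0.936576
    unet  0.999476   0.999738
```

`test_iou` is the macro-mean IoU over the four classes (background, leaf,
rust-like patches, miner tunnels) on the held-out 20 % test split: both
models essentially recover the synthetic scenes (the colour-separable
classes make this an easy task — the benchmark validates the training
machinery, not real-world accuracy). Alongside the table, the run
directory receives per-model `history.csv` (per-epoch loss and validation
Dice/IoU/PA), `metrics.{csv,json}`, per-lesion geometry tables and a
training-curve plot.

The same workflow is scriptable from a shell:

```bash
leafseg generate --config cfg.yaml          # synthetic dataset -> PNG + palette + manifest
leafseg train    --config cfg.yaml
leafseg evaluate --checkpoint runs/.../checkpoint.npz --data data/
leafseg interpret --checkpoint runs/.../checkpoint.npz --data data/
leafseg compare  --config cfg.yaml
```

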