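# pneunet

A lightweight convolutional network for binary pneumonia detection on
frontal chest radiographs, implemented from scratch in numpy — layers,
backward passes and optimizer included — together with its training
protocol, evaluation statistics, Grad-CAM interpretability, and a
seed-controlled synthetic radiograph generator that makes the whole
pipeline testable offline.

It is aimed at people studying lightweight medical-imaging
architectures: the model combines four ideas that each earn their place
in the parameter budget —

* **depthwise-separable convolutions** for the feature-fusion trunk
  (k²·C_in + C_in·C_out multiply-accumulates per position instead of
  k²·C_in·C_out);
* a **squeeze-and-excitation block** that gates the 128 fused channels
  through a Dense(8)→Dense(128)→sigmoid bottleneck after squeezing
  s_c = (1/HW)·Σ_ij x_ijc;
* **atrous spatial pyramid pooling** — parallel 1×1 and 3×3 dilated
  convolutions at rates r ∈ {1, 3, 6}, y[i] = Σ_k x[i + r·k]·w[k],
  concatenated and fused to 128 channels;
* **learnable pooling**, a trainable spatial attention map
  A = σ(conv₁ₓ₁(F)) ∈ (0,1)^{H×W} with F_pooled = Σ (F × A), replacing
  global average pooling so the head can weight lung regions instead of
  averaging them away (a `gap` ablation mode is built in).

Training follows the published recipe — Adam(0.001, β₁=0.9, β₂=0.999),
batch 32, binary cross-entropy with L2 kernel decay λ=0.001, dropout
0.3, early stopping with patience 7 and best-checkpoint selection — and
evaluation reports the confusion matrix (pneumonia positive), per-class
precision/recall/F1 with macro and weighted averages, ROC/AUC, and
McNemar's paired test for comparing classifiers.

## Worked example

Recompute the evaluation table from a test-set confusion matrix
(`python examples/04_published_table_metrics.py`):

```
n = 624 (pneumonia support 390, normal support 234)
accuracy: 0.91
pneumonia: precision 0.91  recall 0.95  f1 0.93  support 390
   normal: precision 0.92  recall 0.83  f1 0.87  support 234
    macro: precision 0.91  recall 0.89  f1 0.9
 weighted: precision 0.91  recall 0.91  f1 0.91

McNemar example (b=15, c=5, corrected): chi2=4.05 p=0.0442 significant=True
```

Reading it: of 390 pneumonia cases 372 were caught (recall 0.95 — the
clinically critical number, since a missed pneumonia is the costly
error), while 39 of 234 normals were over-called (normal recall 0.83).
The McNemar line compares two classifiers on their discordant
predictions: 15-vs-5 splits are lopsided enough to be significant at
α = 0.05.

The other examples each exercise one capability and print what the
numbers mean:

| script | shows |
| --- | --- |
| `examples/01_synthetic_data.py` | phantom generation; mean lung-field intensity separates the classes |
| `examples/02_architecture_audit.py` | per-layer parameter counts (896 … 16,641 … 129) and separable-vs-standard cost |
| `examples/03_train_and_evaluate.py` | end-to-end training on phantoms, history, test metrics |
| `examples/05_gradcam.py` | Grad-CAM heatmap concentrating on the ground-truth opacity |

There is also a CLI for shell use (`pneunet generate | train | evaluate
| compare | explain | summary`); every subcommand writes a
resolved-config JSON next to its outputs so runs can be replayed.

## Synthetic data

`pneunet.data.generate_synthetic` renders simplified chest phantoms:
two darker elliptical lung fields on a bright thorax, Gaussian pixel
noise, and — for the pneumonia class — blurred consolidation-scale
bright opacities confined to the lung fields, with per-image
ground-truth masks retained for localization tests.  One seed fully
determines the dataset.  See `docs/methods.md` for what the phantoms do
and do not emulate.

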