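# polypnet

Colorectal polyps are removed or left in place on the strength of their
optical appearance during colonoscopy.  `polypnet` is a desk-scale,
fully tested implementation of a grayscale-first CNN screening pipeline
for endoscopy stills, aimed at researchers who want to study the
*methodology* — luma preprocessing, a small anchor-grid detector, a
two-class lesion classifier, the center-point evaluation protocol and
its paired statistics — without access to clinical images.  A built-in
synthetic colonoscopy scene generator makes every stage runnable and
reproducible from a single integer seed.

The pipeline:

* **Grayscale conversion** — `Gray = 0.299·R + 0.587·G + 0.114·B`
  (ITU-R BT.601; an alternative "legacy" weight set (0.229, 0.587,
  0.117) used by some published systems is selectable).
* **Detection** — a single-stage CNN on 128×128 inputs: three
  multi-kernel convolution blocks (parallel 3×3 + 3×1 + 1×3 kernels,
  summed) with 2×2/2 pooling down to a 16×16 grid, a 1×1 head emitting
  8 anchors × (objectness, Δx, Δy) per cell, decoded at objectness
  cutoff 0.2 into boxes with fixed anchor dims (16×16 … 216×144,
  180×180 px in frame coordinates).
* **Classification** — a six-block CNN from 480×640 down to 2×3×64 and
  a 2-way softmax: neoplastic (adenoma/carcinoma) vs hyperplastic, at
  cutoff 0.5, ties resolving to the clinically conservative neoplastic
  call.
* **Evaluation** — MICCAI-2015-style center-point criterion (a
  prediction is correct iff its center falls in a ground-truth box),
  image-level accuracy with exact Clopper–Pearson 95% CIs, the
  Acc/Prec/Rec/F1/F2 family, NPV against the 90% diagnose-and-leave
  threshold, ROC/AUC, lesion-size stratification at 1600/1800 px, and
  exact (binomial) McNemar tests for paired arm comparisons.

The CNNs run on a compact numpy engine (tap-wise BLAS convolutions,
explicit backward passes, Adam) — no GPU or deep-learning framework
required.  See `docs/methods.md` for the model details and every design
decision.

## Worked example

Statistics layer on a published-style confusion matrix (neoplastic
positive: TP=118, FN=6, FP=25, TN=31):

```python
>>> from polypnet import ConfusionMatrix2x2, compute_metrics, npv, mcnemar_exact, binomial_ci
>>> cm = ConfusionMatrix2x2(tp=118, fn=6, fp=25, tn=31)
>>> compute_metrics(cm).as_dict()
{'accuracy': 82.8, 'precision': 82.5, 'recall': 95.2, 'f1': 88.4, 'f2': 92.3}
>>> npv(cm)            # 31/37 — below the 90% diagnose-and-leave bar
84.0
>>> mcnemar_exact(0, 3)  # two arms discordant on 3 frames
0.25
>>> binomial_ci(859, 900)  # exact 95% CI for 95.4% detection accuracy
(93.9, 96.7)
```

The metric row reads: 82.8% of test frames classified correctly;
precision 82.5% of neoplastic calls were truly neoplastic; recall 95.2%
of true neoplastic lesions were caught; F2 (92.3) weights that recall
over precision, the right emphasis when a missed adenoma is the costly
error.  An NPV of 84% means leaving "hyperplastic"-called lesions in
place is not yet defensible at the 90% threshold.

End-to-end on synthetic scenes (≈2 minutes at this size):

```bash
polypnet simulate --n 40 --seed 7 --out frames/ --negatives-fraction 0.25
polypnet detect-train --annotations frames/annotations.tsv --out det.npz \
    --channels 1 --epochs 6 --seed 0
polypnet detect-run --weights det.npz --cutoff 0.2 --out preds.tsv frames/*.tif
polypnet evaluate --predictions preds.tsv --annotations frames/annotations.tsv
```

prints:

```
polyp frames: 33/33 detected = 100.0% (95% CI 89.4~100.0)
normal frames: 7/7 clean = 100.00%
```

i.e. every one of the 33 polyp frames had a prediction centered on a
true lesion (the exact binomial CI still spans down to 89.4% at this
sample size) and none of the 7 normal frames drew a spurious box.
`polypnet run-experiment` runs the full two-arm (color vs grayscale)
protocol with a paired exact McNemar comparison and writes
`report.json`.

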