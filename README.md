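# limbseg

Multi-class segmentation of individual lower-limb muscles from stacked
greyscale volumes (T1-weighted-like MRI), as a tested, CPU-only Python
toolkit. It is aimed at researchers in musculoskeletal image analysis who
want to study *architectures and protocol* — in particular spatial-metadata
conditioning of a 2D segmentation network — without a GPU or a clinical
cohort: every stage runs end to end on synthetic limb phantoms.

## What is inside

* **Schema** — 37 named muscle classes (ids 1–37, alphabetical; 0 =
  background) across hips, thigh and calf, with 23 classes flagged for
  accuracy analysis (the rest cannot be segmented manually with acceptable
  repeatability and would bias comparisons).
* **Volume preprocessing** — NIfTI in/out, trilinear resampling to
  isotropic 1 mm (nearest-neighbour for labels), stacking of hip/thigh/
  knee/shank sequences into one hip-to-ankle volume by zero-padding the
  field of view, left-limb reflection, per-muscle mask ↔ label-map
  conversion.
* **Three slice-wise architectures**, implemented from scratch on numpy
  with manual backpropagation:
  * **UNet** — four 3×3-conv encoder stages with 2×2 max pooling, a
    bottleneck, four decoder stages with skip concatenation, 1×1 head,
    per-pixel softmax;
  * **Attention UNet** — a learned multiplicative gate on every skip
    connection (add → ReLU → 1×1 projection → sigmoid → multiply);
  * **SC-UNet** — a *spatial channel* in parallel with the UNet: the
    slice's axial position p ∈ [1, 100] (one-hot, 100 nodes) feeds one
    bias-free fully connected layer (100 → 37) plus sigmoid, producing a
    gate per muscle that multiplies that muscle's predicted probability.
    A muscle that never occurs at a position can thus be switched off for
    that slice. SC-UNet has exactly 100×37 = 3700 more parameters than
    the same-width UNet.
* **Phantoms** — deterministic synthetic subjects (muscle-like intensity
  tubes with characteristic axial extents inside a limb cross-section,
  shape jitter, Gaussian noise) and deformation-augmented "virtual"
  subjects produced by random smooth displacement fields with
  fold-rejection, each tagged with (fixed, moving) provenance.
* **Training protocol** — subject-level leave-one-out splits (80:20
  train/validation of the remainder), exclusion of any augmented subject
  whose provenance names the test subject, mini-batch (8) Adam on
  per-pixel cross entropy, stepped learning rate 1e-3 → 5e-4 (epoch 31)
  → 1e-4 (epoch 61), 90 epochs by default, loss-curve convergence check.
* **Evaluation** — per-muscle relative volume error
  RVE = 100·(V_A − V_R)/V_R (%), Dice coefficient
  DSC = 2|A∩R|/(|A|+|R|), and symmetric surface Hausdorff distance (mm),
  plus Kolmogorov–Smirnov / Kruskal–Wallis / Wilcoxon comparisons across
  models.

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

Train the spatial-channel network on a phantom cohort and evaluate the
held-out subject:

```python
from limbseg.experiments import run_desk_experiment

res = run_desk_experiment("sc_unet", seed=1, epochs=20)
print(res.plan.test_subject, res.plan.train_subjects[:3])
print({k: round(v, 3) for k, v in res.report.summary.items()})
```

Output from this exact call:

```
S11 ('S08', 'S01', 'S02')
{'rve_mean': 0.916, 'rve_sd': 6.732, 'dsc_mean': 0.97, 'dsc_sd': 0.017,
 'hd_mean_mm': 3.449, 'hd_sd_mm': 1.313, 'hd_undefined_count': 0, 'n_classes': 6}
```

Subject `S11` was held out; eight subjects trained the network and two
validated it. Over the six phantom muscles the predicted volumes are
within about one percent of reference on average (mean RVE +0.9 %),
overlap is high (mean DSC 0.97) and the worst surface deviation averages
~3.4 mm — i.e. the spatial-channel network learns position-conditional
multi-class segmentation from scratch in a few CPU-minutes of training at
this scale.

The same pipeline is scriptable from the shell:

```bash
limbseg phantom --n-subjects 11 --out cohort/
limbseg train --cohort cohort/ --variant sc_unet --test-subject S11 --out run/
limbseg evaluate --pred run/S11_pred.nii.gz --ref cohort/S11_labels.nii.gz \
    --n-classes 6 --out run/metrics.csv
```

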