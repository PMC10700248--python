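# ovaseg

Automated segmentation of the two dominant disease sites of high-grade
serous ovarian carcinoma (HGSOC) on contrast-enhanced CT — the bulky
**pelvic/ovarian** lesions (label 1) and the sparse, fat-embedded
**omental** deposits (label 2) — as a complete, CPU-only, dependency-light
pipeline: synthetic phantom cohorts, preprocessing, a four-stage
residual-encoder 3-D U-Net with a tuned optimisation recipe,
Gaussian-weighted sliding-window inference with eight-flip test-time
augmentation, and a full evaluation/statistics battery.

Clinical CT cohorts of this kind are hospital-proprietary.  The package
therefore ships a seedable phantom generator that emulates the cohort
*structure* of the disease — two lesion classes whose component-count
statistics, pre/post-treatment pairing and fat-embedded geometry mirror
the clinical description — so that every stage, from training to paired
statistics, is exercisable and testable end-to-end on one CPU.

## The model

The segmentation network is a U-Net whose encoder is a residual network
with **1, 2, 6 and 3** residual blocks over four stages, 32 filters in the
first stage doubling per stage, instance normalisation and leaky ReLUs;
downsampling uses stride-2 convolutions, sparing the thick-slice axis
while its spacing exceeds 2.5× the in-plane spacing.  A plain six-stage
U-Net ("baseline" variant) is available under the same training and
inference code path, so the tuned-versus-baseline comparison is a config
diff (`presets/paper_model.yaml` vs `presets/nnunet_baseline.yaml`).

Training minimises soft-Dice + cross-entropy (deep supervision over
decoder scales) with SGD, Nesterov momentum 0.98, weight decay 10⁻⁴,
batch size 4, and a linear-warmup + cosine-decay schedule peaking at
lr = 0.02; the baseline recipe is momentum 0.99, weight decay 3·10⁻⁵,
batch size 2 and a polynomial decay from 0.01 to 0 over 250 000 steps.
Inference tiles the volume with overlapping windows, weights each window
with a separable Gaussian (σ = ⅛ window), averages the probabilities of
all 8 axis-flip variants, and restores the argmax labels to the native
grid.  Evaluation reports per-site Dice (DSC, 0–100), sensitivity,
precision, physical volumes, 26-connected component counts, cross-site
label confusion, Bland–Altman volume agreement, and exact paired Wilcoxon
signed-rank tests; metrics are computed only on scans whose ground truth
contains the site.

The network/optimiser stack is implemented directly on numpy (im2col
convolutions, analytic backpropagation), so the package runs anywhere
scientific Python runs; all presets are sized for a single CPU.

## Worked example

```bash
ovaseg run all --config tiny --out runs/demo
```

This generates a 10-patient × 2-scan phantom cohort (8 patients for
training, 2 held out), preprocesses to (5.0, 1.4, 1.4) mm, trains the
tuned-variant network at phantom scale (8 base filters, 1000 steps,
patch 16³), predicts the 4 held-out scans with sliding-window + flip-TTA,
and evaluates.  It finishes in a few minutes on one CPU and prints:

```
pelvic_ovarian: DSC 94 ± 1 (n=4)
omental: DSC 91 ± 2 (n=4)
ok
```

i.e. on held-out phantoms the bulky pelvic/ovarian site and the
fat-embedded omental site are both segmented with mean DSC in the low
90s (the fat band gives the omental deposits ~160 HU of contrast, which
at phantom scale compensates their sparsity).  `runs/demo/report/`
contains the per-scan metrics CSV, the aggregate JSON (including
Bland–Altman volume bias and bottom-quartile outlier slices) and the
Bland–Altman data CSV; `runs/demo/resolved_config.yaml` and
`run_log.jsonl` record the exact configuration and seeds, and a rerun
with the same seed reproduces the metrics byte-for-byte.

Individual stages are available as `ovaseg phantom|preprocess|train|
predict|evaluate`, and the model is also exposed as a scikit-learn style
estimator:

```python
from ovaseg.estimator import LesionSegmenter
seg = LesionSegmenter(total_steps=1000).fit(volumes, labelmaps)
predictions = seg.predict(test_volumes)   # native-grid LabelMaps
```

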