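# datnorm

Intensity normalization for DaTSCAN (¹²³I-ioflupane) SPECT brain
volumes, and the evaluation harness to judge whether a normalization
worked.

In DaT imaging the striatum lights up in healthy brains and dims —
often asymmetrically — in Parkinsonian syndrome (PS).  Before
voxel-wise comparison or computer-aided diagnosis, per-subject
intensity differences caused by camera calibration (a gain *α* and an
offset *β*) must be removed without touching the diagnostic striatal
signal.  `datnorm` provides, for neuroimaging researchers working with
co-registered functional volumes:

* **FGMM** — spatial Gaussian-mixture filtering: model the image as
  I·p(**x**) with p a k-component Gaussian mixture over voxel
  coordinates fitted by intensity-weighted EM; zero out every component
  whose density falls below the uniform threshold η = 1/N on ≥ 75 % of
  striatal voxels; reconstruct from the survivors.  Preserves the
  striatum, suppresses (and thereby normalizes) the background.
* **MSE** — closed-form linear normalization: Î = a·I + b with
  a = (Σ I·T − N m_T m_I)/(Σ I² − N m_I²), b = m_T − a·m_I, minimizing
  the mean squared error against a symmetric control template over the
  non-specific (brain-minus-striatum) region.
* **BR_all** — the specific-to-non-specific binding-ratio baseline,
  BP = C_VOI/C_N − 1, applied voxel-wise.
* A **phantom generator** producing co-registered DaTSCAN-like cohorts
  with known ground-truth gain/offset corruption, so every stage is
  testable without clinical data.
* **Evaluation**: per-subject Kullback–Leibler divergence of
  non-specific histograms against the cohort mean (D_KL(P‖Q) =
  Σ P ln(P/Q)), percentile histogram bands, and a leave-one-out
  linear-SVM classification harness (voxels-as-features and PCA).

## Worked example

Run the bundled 40-subject phantom study (simulate → template/masks →
normalize with every method → evaluate → classify) from Python:

```python
from datnorm.phantom import generate_phantom
from datnorm.pipeline import study_config, normalize_all, kl_tables, classification_tables

config = study_config(seed=1)
cohort, truth = generate_phantom(config.phantom)
cohorts, fits, template, masks = normalize_all(cohort, config)

_, kl = kl_tables(cohorts, masks)
print(kl[kl["class"] == "NC+PS"][["method", "mean", "sd"]].to_string(index=False))
print(classification_tables(cohorts, config).to_string(index=False))
```

which prints (seed 1):

```
method     mean       sd
   raw 2.841726 4.090696
 brall 0.379076 0.090248
  fgmm 0.086830 0.102061
   mse 0.234878 0.077846

method features  accuracy  sensitivity  specificity
   raw      vaf     100.0        100.0        100.0
   raw      pca      80.0         85.0         75.0
 brall      vaf     100.0        100.0        100.0
 brall      pca     100.0        100.0        100.0
  fgmm      vaf      92.5         95.0         90.0
  fgmm      pca      87.5         85.0         90.0
   mse      vaf     100.0        100.0        100.0
   mse      pca     100.0        100.0        100.0
```

Reading the first table: the mean KL divergence measures how far each
subject's non-specific histogram sits from the cohort mean — raw
(uncorrected) images are wildly heterogeneous (2.84), the binding-ratio
baseline removes the gain but not the offset (0.38), while FGMM (0.087)
and MSE (0.235) produce the homogeneous cohorts the methods are
designed for.  The second table shows the downstream diagnostic
readout; on this synthetic cohort the anatomy is identical across
subjects, so absolute accuracies are near ceiling and only the
relative ordering is informative.

The same study is available from the shell:

```
datnorm run --out runs/demo --seed 1
```

and individual stages as `datnorm simulate | build-template |
make-masks | normalize | evaluate | classify` (see `--help`).

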