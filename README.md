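# imfquant

Automated quantification of intramuscular fat (IMF) in muscle regions of
interest from axial MRI, by thresholding the within-ROI T2-weighted
intensity histogram — together with the Dixon fat–water reference and the
full agreement-evaluation framework used to compare thresholding models
against it.

The package is aimed at musculoskeletal imaging researchers who segment
muscles (e.g. the lumbar multifidus, erector spinae and psoas major, left
and right: labels `LML, LMR, ESL, ESR, PML, PMR`) on axial scans and need a
reproducible, operator-independent estimate of fat infiltration.

## Models

Within each muscle ROI the voxel intensities `x_1..x_n` are modelled as

* a **Gaussian mixture** `p(x) = Σ_k π_k N(x | μ_k, σ_k²)` fitted by EM, or
* **K-means** clusters fitted by Lloyd's algorithm with greedy k-means++
  seeding,

with `k = 2` components (muscle, fat) or `k = 3` (muscle, *undefined*,
fat), where the undefined class captures the partial-volume zone of
intermediate intensities.  Each fit is restarted 50 times (max 1000
iterations, tolerance 0.001) and the best-scoring restart kept.  Components
sorted by ascending mean are mapped to tissue classes; decision thresholds
are the midpoints of adjacent K-means centers, or the posterior-crossing
points of adjacent Gaussian components (the Bayes boundary of the fitted
mixture).  IMF is then the voxel-count fraction

    IMF_T2 = 100 · Volume_fat / (Volume_fat + Volume_muscle)

with undefined voxels assigned to fat.  The reference standard uses the
within-ROI mean Dixon signals:

    IMF_Dixon = 100 · S_fat / (S_fat + S_water)

Agreement of the four models (`GMM2C, KMEANS2C, GMM3C, KMEANS3C`) with the
Dixon reference is evaluated per muscle with Bland–Altman bias and 95%
limits of agreement, the consistency intraclass correlation ICC(3,1) with
the standard reliability bands (0.50/0.75/0.90), the mean absolute error,
a 2×2 within-subject ANOVA (algorithm × component count) on absolute
errors, and post-hoc paired t-tests.

A phantom generator produces synthetic muscle samples with a known
ground-truth fat fraction — pure muscle and fat modes plus a configurable
partial-volume zone — and perfectly registered Dixon signals, so the whole
pipeline can be validated end to end against an exact reference.

## Worked example

```python
from imfquant import PhantomSpec, generate_subject, quantify_muscle, reference_imf

spec = PhantomSpec(n_voxels=2500, true_fat_fraction=0.30, pv_fraction=0.15, seed=7)
subject = generate_subject(spec)
print(f"Dixon reference IMF: {reference_imf(subject):.2f}%")
for model_id in ("GMM2C", "KMEANS2C", "GMM3C", "KMEANS3C"):
    res = quantify_muscle(subject.t2_sample, model_id, seed=0)
    print(model_id, f"{res.imf_percent:.2f}%", res.thresholds)
```

prints

```
Dixon reference IMF: 30.76%  (ground truth 30.76%)
GMM2C     IMF 33.84%  thresholds [190.2]  (muscle 1654, undefined 0, fat 846)
KMEANS2C  IMF 31.32%  thresholds [242.7]  (muscle 1717, undefined 0, fat 783)
GMM3C     IMF 34.52%  thresholds [176.6, 317.6]  (muscle 1637, undefined 212, fat 651)
KMEANS3C  IMF 34.08%  thresholds [183.8, 332.5]  (muscle 1648, undefined 225, fat 627)
```

The phantom's muscle mode sits at 100 a.u. and its fat mode at 400 a.u.;
15% of voxels are partial-volume mixtures.  Each model reports its
effective intensity threshold(s) and class counts; the three-component
models carve out an explicit undefined zone (here ≈220 voxels) that is
counted as fat.

The same operations are available from the shell:

```sh
imfquant simulate --law multifidus --n-subjects 30 --out sim/
imfquant quantify --volume t2.nii.gz --mask lml.nii.gz --muscle LML --out imf.csv
imfquant evaluate --results imf.csv --reference dixon.csv --out report/
imfquant run-study --config study.yaml --out out/   # end-to-end + figures
```

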