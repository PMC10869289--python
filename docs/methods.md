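# Methods

## Problem and data model

A muscle ROI on an axial T2-weighted volume yields a 1-D sample of voxel
intensities.  Fat is bright on T2, muscle dark, and voxels straddling the
tissue boundary (or containing diffuse intramyocellular lipid) take
intermediate values — the *undefined zone*.  The package estimates the
fat fraction of the ROI by partitioning this intensity histogram, and
validates the estimate against the Dixon fat–water fat fraction, which is
treated as the reference standard throughout.

Intensities are used raw: no rescaling, histogram equalisation or
bias-field correction, and masks are never resampled between acquisition
grids — a T2 volume and a Dixon pair each carry their own segmentation,
enforced by an opaque `grid_id` derived from shape and affine.  Every voxel
inside a mask counts equally; slice thickness does not weight voxels within
a grid.

## Mixture fitting

Both fitters are univariate and written for exact reproducibility.

**GMM / EM.** Standard EM on `p(x) = Σ_k π_k N(x | μ_k, σ_k²)`; in one
dimension a "full" covariance is simply an unconstrained per-component
variance.  Initialisation follows the k-means method: one Lloyd run (itself
greedy-k-means++-seeded from the restart's RNG stream) supplies the initial
partition, from which means, within-cluster variances and occupancy weights
are taken.  Convergence is declared when the mean per-sample log-likelihood
improves by less than `tol` (default 0.001); the iteration cap is 1000.
Variances are floored at `var_floor_frac` (default 1e-6) times the sample
variance so spiky histograms cannot produce singular components; the floor
is the package's own degeneracy guard.  Components that still collapse to
coincident means raise a degenerate-fit error rather than returning an
arbitrary ordering.

**K-means.** Lloyd iterations with greedy k-means++ seeding (each new
center chosen among `2 + ⌊log k⌋` distance-weighted candidates, keeping the
one that most reduces the potential — the refinement used by the major
library implementations, which materially improves best-of-n restart
coverage in 1-D).  An emptied cluster is re-seeded at the point farthest
from its assigned center (deterministic, ties to the lowest index).
Iteration stops at an unchanged assignment (exact fixed point) or when the
within-cluster sum of squares decreases by less than a relative `tol`
(default 0.001).

**Restarts.** `fit_best` runs `n_init = 50` independent fits, restart `i`
seeded with `seed + i`, and keeps the maximal score — total log-likelihood
for the GMM, negative within-cluster SS for K-means (ties go to the lowest
restart index).  Everything downstream is therefore bit-reproducible given
a seed.  Per-fit seeds in the study runner are derived from the study seed
and the (subject, muscle, model) coordinates by CRC32, so they are stable
across platforms and any single fit can be re-run in isolation.

## Classification and IMF

Components sorted by ascending mean map to (muscle, fat) or (muscle,
undefined, fat).  Thresholds: K-means uses midpoints of adjacent centers
(the nearest-center rule); the GMM uses the crossing of adjacent weighted
component densities, located by bisection between the two means — the
Bayes decision boundary of the fitted mixture, which also yields reportable
cut points for histogram figures.  Labels are then assigned by interval
membership against the thresholds, which guarantees a label map monotone in
intensity; a voxel exactly at a threshold goes to the higher (fat-side)
class.  If adjacent weighted densities never change order between their
means (possible when a broad heavy component dominates everywhere), the
classification falls back to per-voxel argmax with thresholds reported as
undefined, and a warning.

`IMF_T2 = 100·(n_fat + n_undefined)/n_total`: the undefined zone is
assigned to fat, on the hypothesis that intermediate voxels carry
substantial fat through partial-volume mixing; the denominator is the whole
ROI.  The Dixon route averages fat and water signals over the ROI first and
then forms `100·S_fat/(S_fat + S_water)`; this mean-of-signals convention
differs in general from averaging voxel-wise fat fractions and is the
deliberate choice.

## Agreement statistics

* Bland–Altman: bias = mean(model − reference), SD with n−1, limits of
  agreement at bias ± 1.96 SD.  Negative bias means the model
  underestimates the reference.
* ICC(3,1): two-way mixed-effects, single-measurement, **consistency**
  form, `(MS_R − MS_E)/(MS_R + (k−1)MS_E)` from the subjects × raters ANOVA
  without interaction.  The absolute-agreement variant is explicitly not
  used: a constant offset between model and reference leaves the
  consistency ICC at 1.  Negative values are returned as computed.  Bands:
  poor < 0.50 ≤ moderate < 0.75 ≤ good < 0.90 ≤ excellent.
* 2×2 repeated-measures ANOVA on per-subject absolute errors with factors
  algorithm (GMM vs K-means) and components (2 vs 3).  Each 2-level effect
  is tested against its own subject-by-effect error term with (1, n−1) df,
  which is numerically identical to the squared paired t of the effect's
  contrast scores.  Sphericity is trivially satisfied for 2-level factors
  and reported as not applicable.  Zero-variance contrasts are flagged
  degenerate (F = 0 for a null effect, F = ∞ for a perfectly constant
  nonzero one) instead of silently producing NaNs.
* Post-hoc paired t-tests compare the lowest-MAE model against the other
  three, two-sided, unadjusted by default; a Holm step-down adjustment is
  available behind a flag.  Unadjusted p-values reproduce the plain
  post-hoc procedure; the flag exposes the safer option.
* Normality diagnostics (Shapiro–Wilk) are delegated to scipy behind the
  `--diagnostics` flag rather than re-implemented.

Left and right muscles are always treated as separate series, and
thresholds are fitted per muscle per subject — never pooled.

## Phantom generator

Each voxel carries a fat proportion `f`: pure fat (`f = 1`) with
probability `p_f`, pure muscle (`f = 0`) with probability `p_m`, or a
partial-volume mixture with `f` drawn from a mixing law.  `p_f` and `p_m`
are solved so the expected fat volume equals the requested ground truth;
an unsatisfiable request (e.g. a lean muscle with a fat-heavy PV law) is a
constraint error.  The T2 intensity of a voxel is
`N(f·μ_fat + (1−f)·μ_muscle, f·σ_fat² + (1−f)·σ_muscle²)` — variances are
blended linearly in `f`, the simplest mixture-of-profiles choice, exposed
as a knob via the mode parameters.  Dixon signals are `f·S` and `(1−f)·S`
with `S = 1000` a.u. (only the ratio matters; scale invariance is asserted
in tests), plus optional additive Gaussian noise.  With zero noise the
ROI-mean Dixon fat fraction equals `100·mean(f)` *exactly*, anchoring the
evaluation to a machine-precision reference.

Defaults: 2500 voxels per muscle (a realistic multi-slice lumbar ROI),
muscle mode 100 ± 25 a.u., fat mode 400 ± 40 a.u. — mimicking a 16-bit
T2-weighted acquisition spanning grey values ≈0–500, with ≥ 6 SD mode
separation so that fatty muscles are clearly bimodal.  Cohort laws:

* *multifidus-like*: true fat fraction ~ U(0.10, 0.50), PV fraction 0.15,
  PV mixing law uniform(0, 1);
* *psoas-like*: true fat fraction ~ U(0.01, 0.08), PV fraction 0.15, PV
  mixing law Beta(1, 19) (mean 0.05) — lean-muscle boundary voxels are
  predominantly muscle, and a symmetric law would by itself imply more fat
  than the lean ground truth allows.

T2 and Dixon phantom voxels are perfectly registered, unlike typical
two-sequence acquisitions; the generator does not emulate scanner physics
(coil sensitivity, bias fields) beyond additive noise, nor anatomical 3-D
muscle shapes.

### What the phantom shows — and does not

On bimodal phantoms without partial volume, all four models recover the
ground truth within a percentage point.  On lean, near-unimodal phantoms
the three-component models split the muscle mode and overestimate IMF
grossly (cohort bias > +10 points, ICC collapsing), while two-component
models stay accurate — reproducing the characteristic multi-component
failure mode on lean muscles such as the psoas major, where the extra
components overfit the variance of a single intensity mode.

On the fatty cohort the generator does *not* reproduce the empirical
superiority of the three-component GMM seen on patient data.  Because the
phantom's PV law is symmetric and its pure voxels carry no fat signal, a
calibrated two-class threshold at the PV midpoint is nearly unbiased by
construction (measured K-means-2C MAE ≈ 0.5 points), whereas counting the
whole undefined zone as fat overestimates by ≈ pv·(1 − E[f | captured])
(measured GMM-3C bias ≈ +4 points).  The real-data advantage of the
three-component approach rests on histogram features this generative model
deliberately omits — fat signal inside nominally pure muscle voxels
(intramyocellular lipid) and weak, broad fat modes that pull two-class
thresholds deep into the fat tail.  Passing the phantom tests therefore
validates the machinery (fitting, thresholding, statistics, determinism),
not the clinical ranking of the models.

## Numerical choices

* GMM score is the total log-likelihood; convergence is monitored on the
  mean per-sample log-likelihood, matching the tolerance semantics of the
  common library EM implementations.
* Posterior crossings are bisected to ~1e-12 relative tolerance; the
  independent check scans the posterior argmax on a 0.01-intensity grid.
* The K-means/EM restart scheme (`seed + i`) and CRC32-derived study seeds
  keep every random draw attributable and reproducible across platforms.
* Ties at thresholds go to the fat side; ties in restart score go to the
  lowest restart index; empty-cluster re-seeding ties go to the lowest
  voxel index.  All three rules are bit-stable.
* Samples with zero variance, fewer distinct values than clusters, or
  collapsing components raise typed errors; `fit_best` aggregates restart
  failures and only errors when every restart degenerates.

## Known limitations

* The thresholding models assume the histogram modes correspond to
  tissues; on lean muscles the 3-component variants are structurally
  biased upward (by design, this is reproduced, not corrected).
* The Dixon reference is itself an estimate on real data; the exact
  ground-truth identity holds only for noiseless phantoms.
* The study runner evaluates each muscle series independently and does not
  model between-muscle correlation within subjects.
* Multivariate mixtures, automatic component-count selection, Otsu
  thresholding, DICOM ingestion and inter-sequence registration are out of
  scope.
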