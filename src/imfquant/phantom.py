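"""Synthetic muscle phantoms with known ground-truth fat fraction.

Each phantom voxel carries a fat proportion ``f``: pure muscle (f = 0),
pure fat (f = 1), or a partial-volume mixture with ``f`` drawn from a mixing
law (default uniform on (0, 1)).  The T2-weighted intensity of a voxel is
drawn from a Gaussian whose mean interpolates linearly between the muscle
and fat modes with ``f`` and whose variance interpolates linearly between
the mode variances.  Pure-tissue fractions are solved so that the expected
total fat volume matches the requested ground truth given the partial-
volume fraction and the mixing law's mean.

Dixon signals are generated as ``fat = f * S`` and ``water = (1 - f) * S``
for a fixed total signal S (1000 a.u.), plus optional additive Gaussian
noise; with zero noise the ROI-mean Dixon fat fraction equals the realised
ground truth ``100 * mean(f)`` exactly, which anchors the whole evaluation
framework to an exact reference.

The default intensity modes (muscle 100 +/- 25, fat 400 +/- 40 a.u.) mimic a
16-bit T2-weighted acquisition whose grey values span roughly 0-500: a
clearly bimodal histogram for fatty muscles, with the partial-volume
"undefined zone" filling the intermediate intensities.  Lean, psoas-like
muscles (true fat fraction of a few percent) produce near-unimodal
histograms, the regime in which multi-component thresholding is expected
to overfit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import IntensitySample, IntensityVolume, MuscleROI
from .thresholding import dixon_fat_fraction

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "CohortLaw",
    "generate_subject",
    "generate_cohort",
    "multifidus_like_law",
    "psoas_like_law",
    "subject_to_volumes",
]

#: Fixed total Dixon signal per voxel (arbitrary units); only the fat/water
#: ratio matters to the fat fraction.
DIXON_TOTAL_SIGNAL = 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one muscle sample.

    ``pv_mix_law`` is either ``"uniform"`` or ``("beta", a, b)`` and gives
    the distribution of the fat proportion f of partial-volume voxels.
    """

    n_voxels: int = 2500
    true_fat_fraction: float = 0.30
    pv_fraction: float = 0.15
    mu_muscle: float = 100.0
    sigma_muscle: float = 25.0
    mu_fat: float = 400.0
    sigma_fat: float = 40.0
    pv_mix_law: object = "uniform"
    dixon_noise_sd: float = 0.0
    muscle_label: str = "LML"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_fat <= self.mu_muscle:
            raise ValueError("fat mode must be brighter than muscle mode")
        if self.sigma_muscle <= 0 or self.sigma_fat <= 0:
            raise ValueError("mode standard deviations must be positive")
        if not (0 <= self.true_fat_fraction <= 1 and 0 <= self.pv_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_voxels < 1:
            raise ValueError("need at least one voxel")

    @property
    def pv_mean_f(self) -> float:
        """Expected fat proportion of a partial-volume voxel under the law."""
        law = self.pv_mix_law
        if law == "uniform":
            return 0.5
        if isinstance(law, tuple) and law[0] == "beta":
            _, a, b = law
            return a / (a + b)
        raise ValueError(f"unknown pv_mix_law {law!r}")

    def pure_fractions(self) -> tuple[float, float]:
        """(p_fat, p_muscle) solving the expected-fat-volume constraint."""
        p_fat = self.true_fat_fraction - self.pv_fraction * self.pv_mean_f
        p_muscle = 1.0 - self.pv_fraction - p_fat
        if p_fat < -1e-12 or p_muscle < -1e-12:
            raise ValueError(
                f"infeasible phantom: true_fat_fraction={self.true_fat_fraction} "
                f"incompatible with pv_fraction={self.pv_fraction} and "
                f"E[f]={self.pv_mean_f}"
            )
        return max(p_fat, 0.0), max(p_muscle, 0.0)


@dataclass(frozen=True)
class PhantomSubject:
    """One generated muscle sample with aligned T2 and Dixon signals."""

    t2_sample: IntensitySample
    dixon_fat_sample: np.ndarray
    dixon_water_sample: np.ndarray
    fat_proportions: np.ndarray
    true_imf_percent: float
    spec: PhantomSpec


def _draw_mix_proportions(spec: PhantomSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    law = spec.pv_mix_law
    if law == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if isinstance(law, tuple) and law[0] == "beta":
        _, a, b = law
        return rng.beta(a, b, size=n)
    raise ValueError(f"unknown pv_mix_law {law!r}")


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Draw one phantom muscle; deterministic under ``spec.seed``.

    The realised ground truth is ``100 * mean(f)`` over the drawn voxels, so
    the noiseless Dixon identity holds exactly rather than only in
    expectation.
    """
    rng = np.random.default_rng(spec.seed)
    p_fat, p_muscle = spec.pure_fractions()
    kind = rng.choice(3, size=spec.n_voxels, p=[p_muscle, spec.pv_fraction, p_fat])

    f = np.zeros(spec.n_voxels)
    f[kind == 2] = 1.0
    n_pv = int(np.sum(kind == 1))
    if n_pv:
        f[kind == 1] = _draw_mix_proportions(spec, n_pv, rng)

    mean_t2 = f * spec.mu_fat + (1.0 - f) * spec.mu_muscle
    var_t2 = f * spec.sigma_fat**2 + (1.0 - f) * spec.sigma_muscle**2
    t2 = rng.normal(mean_t2, np.sqrt(var_t2))

    fat = f * DIXON_TOTAL_SIGNAL
    water = (1.0 - f) * DIXON_TOTAL_SIGNAL
    if spec.dixon_noise_sd > 0:
        fat = fat + rng.normal(0.0, spec.dixon_noise_sd, size=spec.n_voxels)
        water = water + rng.normal(0.0, spec.dixon_noise_sd, size=spec.n_voxels)

    return PhantomSubject(
        t2_sample=IntensitySample(values=t2, muscle_label=spec.muscle_label),
        dixon_fat_sample=fat,
        dixon_water_sample=water,
        fat_proportions=f,
        true_imf_percent=100.0 * float(np.mean(f)),
        spec=spec,
    )


@dataclass(frozen=True)
class CohortLaw:
    """Per-subject randomisation of the phantom parameters.

    ``true_fat_fraction`` is drawn uniformly from ``fat_fraction_range``;
    all other parameters are shared across subjects.
    """

    fat_fraction_range: tuple[float, float] = (0.10, 0.50)
    base_spec: PhantomSpec = PhantomSpec()
    name: str = "multifidus-like"


def multifidus_like_law(**overrides) -> CohortLaw:
    """Fatty paraspinal muscle: true fat fraction 10-50%, PV zone 15%."""
    base = replace(PhantomSpec(), pv_fraction=0.15, muscle_label="LML")
    return CohortLaw(fat_fraction_range=(0.10, 0.50),
                     base_spec=replace(base, **overrides),
                     name="multifidus-like")


def psoas_like_law(**overrides) -> CohortLaw:
    """Lean muscle: true fat fraction 1-8%, near-unimodal histogram.

    Partial-volume voxels of a lean muscle are predominantly muscle with a
    small lipid content, so their fat proportion follows Beta(1, 19)
    (mean 0.05) rather than the uniform law of fatty muscles; a uniform law
    would by itself imply more fat than the lean ground truth allows.
    """
    base = replace(
        PhantomSpec(),
        pv_fraction=0.15,
        pv_mix_law=("beta", 1.0, 19.0),
        muscle_label="PML",
    )
    return CohortLaw(fat_fraction_range=(0.01, 0.08),
                     base_spec=replace(base, **overrides),
                     name="psoas-like")


def generate_cohort(
    n_subjects: int, law: CohortLaw, seed: int = 0
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate ``n_subjects`` phantoms under a cohort law.

    Per-subject specs (ground-truth fat fraction and RNG seed) are derived
    deterministically from ``seed``.  Returns the subjects and a ground-
    truth table (subject_id, muscle_label, true_imf_percent).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    lo, hi = law.fat_fraction_range
    fractions = rng.uniform(lo, hi, size=n_subjects)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    subjects = []
    rows = []
    for i in range(n_subjects):
        spec = replace(
            law.base_spec,
            true_fat_fraction=float(fractions[i]),
            seed=int(subject_seeds[i]),
        )
        subj = generate_subject(spec)
        subjects.append(subj)
        rows.append(
            {
                "subject_id": f"S{i:03d}",
                "muscle_label": spec.muscle_label,
                "true_imf_percent": subj.true_imf_percent,
            }
        )
    return subjects, pd.DataFrame(rows)


def reference_imf(subject: PhantomSubject) -> float:
    """Dixon reference IMF (%) of a phantom from its generated signals."""
    return dixon_fat_fraction(subject.dixon_fat_sample, subject.dixon_water_sample)


def subject_to_volumes(
    subject: PhantomSubject,
) -> tuple[IntensityVolume, IntensityVolume, IntensityVolume, MuscleROI]:
    """Pack a phantom into NIfTI-ready volumes (T2, Dixon fat, Dixon water)
    plus the ROI mask selecting its voxels.

    Voxels are laid out row-major into the smallest cube that holds them;
    padding voxels are zero and outside the mask.  Round-tripping through
    volume I/O and ROI extraction reproduces the original samples.
    """
    n = subject.t2_sample.n_voxels
    side = int(np.ceil(n ** (1.0 / 3.0)))
    shape = (side, side, max(1, int(np.ceil(n / side**2))))
    size = int(np.prod(shape))

    def pack(values: np.ndarray) -> np.ndarray:
        flat = np.zeros(size)
        flat[:n] = np.maximum(values, 0.0)  # volumes are non-negative carriers
        return flat.reshape(shape)

    mask = np.zeros(size, dtype=bool)
    mask[:n] = True
    grid = f"phantom-{subject.spec.seed}-{shape}"
    spacing = (1.0, 1.0, 1.0)
    t2 = IntensityVolume(pack(subject.t2_sample.values), spacing, grid)
    fat = IntensityVolume(pack(subject.dixon_fat_sample), spacing, grid)
    water = IntensityVolume(pack(subject.dixon_water_sample), spacing, grid)
    roi = MuscleROI(
        label=subject.spec.muscle_label, mask=mask.reshape(shape), grid_id=grid
    )
    return t2, fat, water, roi
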