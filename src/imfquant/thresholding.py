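"""Voxel classification and intramuscular-fat (IMF) computation.

A fitted mixture is turned into tissue classes by ascending mean: with two
components the classes are (muscle, fat); with three, (muscle, undefined,
fat), where the middle "undefined zone" holds intermediate intensities of
mixed muscle/fat content.  Classification is expressed as interval
membership against explicit intensity thresholds, so the label map is
guaranteed monotone in intensity:

* K-means thresholds are midpoints of adjacent sorted centers (the nearest-
  center rule in 1-D).
* GMM thresholds are the posterior-crossing points between adjacent
  components — the Bayes decision boundary for the fitted model — located
  by bisection between adjacent means.

IMF is then computed two ways:

* T2 route: ``IMF = 100 * Volume_fat / (Volume_fat + Volume_muscle)`` as a
  voxel-count fraction, with undefined voxels assigned to fat (they are
  assumed to carry substantial fat through partial-volume mixing).
* Dixon route: ``IMF = 100 * S_fat / (S_fat + S_water)`` from the within-ROI
  average fat and water signals; this is the reference standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import bisect

from .core import DixonPair, IntensitySample, MuscleROI, extract_roi_sample
from .mixtures import (
    GmmConfig,
    KmeansConfig,
    MixtureFit,
    _weighted_log_densities,
    fit_best,
)

__all__ = [
    "MUSCLE",
    "UNDEFINED",
    "FAT",
    "MODEL_IDS",
    "VoxelClassification",
    "ImfResult",
    "classify_sample",
    "imf_t2",
    "imf_dixon",
    "dixon_fat_fraction",
    "quantify_muscle",
    "run_model",
]

MUSCLE, UNDEFINED, FAT = 0, 1, 2
CLASS_NAMES = {MUSCLE: "muscle", UNDEFINED: "undefined", FAT: "fat"}

#: The four compared thresholding models.
MODEL_IDS = ("GMM2C", "KMEANS2C", "GMM3C", "KMEANS3C")
_MODEL_SPECS = {
    "GMM2C": ("gmm", 2),
    "KMEANS2C": ("kmeans", 2),
    "GMM3C": ("gmm", 3),
    "KMEANS3C": ("kmeans", 3),
}


@dataclass(frozen=True)
class VoxelClassification:
    """Per-voxel tissue labels aligned with the sample's voxel order.

    ``thresholds`` holds 1 (two-component) or 2 (three-component) ascending
    intensity cut points; it is ``None`` when no monotone decision boundary
    exists and labels fell back to per-voxel argmax.  A voxel exactly at a
    threshold is assigned to the higher (fat-side) class.
    """

    labels: np.ndarray
    thresholds: tuple[float, ...] | None
    model_id: str

    def count(self, cls: int) -> int:
        return int(np.sum(self.labels == cls))

    @property
    def n_total(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ImfResult:
    """IMF percentage for one muscle under one model (or the Dixon reference)."""

    muscle_label: str
    model_id: str
    imf_percent: float
    n_voxels_muscle: int = 0
    n_voxels_undefined: int = 0
    n_voxels_fat: int = 0
    thresholds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.imf_percent <= 100.0:
            raise ValueError(f"IMF {self.imf_percent} outside [0, 100]%")


def _gmm_crossing(fit: MixtureFit, lo_idx: int) -> float | None:
    """Posterior crossing between components ``lo_idx`` and ``lo_idx+1``.

    Solves ``pi_j N(x|mu_j, s_j) == pi_{j+1} N(x|mu_{j+1}, s_{j+1})`` by
    bisection on [mu_j, mu_{j+1}]; returns None when the weighted densities
    do not change order between the two means.
    """
    means = np.asarray(fit.means)
    variances = np.asarray(fit.variances)
    weights = np.asarray(fit.weights)

    def diff(x: float) -> float:
        ld = _weighted_log_densities(
            np.atleast_1d(float(x)), means, variances, weights
        )[0]
        return float(ld[lo_idx + 1] - ld[lo_idx])

    a, b = fit.means[lo_idx], fit.means[lo_idx + 1]
    fa, fb = diff(a), diff(b)
    if not (fa < 0 < fb):
        return None
    xtol = max(1e-12, 1e-12 * (b - a))
    return float(bisect(diff, a, b, xtol=xtol))


def classify_sample(fit: MixtureFit, sample: IntensitySample) -> VoxelClassification:
    """Map each voxel of the sample to {muscle, undefined, fat}.

    Components sorted by ascending mean become (muscle, fat) for 2-component
    fits and (muscle, undefined, fat) for 3-component fits.  Labels are
    assigned by interval membership against the effective thresholds, which
    keeps the class monotone in intensity.
    """
    k = fit.n_components
    model_id = f"{'GMM' if fit.model_kind == 'gmm' else 'KMEANS'}{k}C"
    if fit.model_kind == "kmeans":
        thresholds = tuple(
            (fit.means[j] + fit.means[j + 1]) / 2.0 for j in range(k - 1)
        )
    else:
        found = [_gmm_crossing(fit, j) for j in range(k - 1)]
        if any(t is None for t in found) or any(
            b <= a for a, b in zip(found, found[1:])
        ):
            warnings.warn(
                f"{model_id}: no monotone posterior boundary between adjacent "
                "components; falling back to per-voxel argmax with undefined "
                "thresholds",
                stacklevel=2,
            )
            wlog = _weighted_log_densities(
                sample.values,
                np.asarray(fit.means),
                np.asarray(fit.variances),
                np.asarray(fit.weights),
            )
            comp = np.argmax(wlog, axis=1)
            labels = _component_to_class(comp, k)
            return VoxelClassification(labels=labels, thresholds=None, model_id=model_id)
        thresholds = tuple(float(t) for t in found)

    # voxel exactly at a threshold goes to the higher (fat-side) class
    comp = np.searchsorted(np.asarray(thresholds), sample.values, side="right")
    labels = _component_to_class(comp, k)
    return VoxelClassification(labels=labels, thresholds=thresholds, model_id=model_id)


def _component_to_class(comp: np.ndarray, k: int) -> np.ndarray:
    if k == 2:
        return np.where(comp == 0, MUSCLE, FAT).astype(np.int8)
    return comp.astype(np.int8)  # 0, 1, 2 already mean muscle, undefined, fat


def imf_t2(classification: VoxelClassification, muscle_label: str = "") -> ImfResult:
    """Volume-fraction IMF from a T2 classification; undefined counts as fat."""
    n_m = classification.count(MUSCLE)
    n_u = classification.count(UNDEFINED)
    n_f = classification.count(FAT)
    n_total = classification.n_total
    if n_total == 0:
        raise ValueError("empty classification")
    return ImfResult(
        muscle_label=muscle_label,
        model_id=classification.model_id,
        imf_percent=100.0 * (n_f + n_u) / n_total,
        n_voxels_muscle=n_m,
        n_voxels_undefined=n_u,
        n_voxels_fat=n_f,
        thresholds=classification.thresholds,
    )


def dixon_fat_fraction(fat_values: np.ndarray, water_values: np.ndarray) -> float:
    """Fat fraction (%) from paired fat/water signal samples via ROI means."""
    mean_fat = float(np.mean(fat_values))
    mean_water = float(np.mean(water_values))
    total = mean_fat + mean_water
    if total <= 0:
        raise ValueError("zero total Dixon signal inside ROI: fat fraction undefined")
    return 100.0 * mean_fat / total


def imf_dixon(pair: DixonPair, roi: MuscleROI) -> ImfResult:
    """Reference IMF from the within-ROI average Dixon fat and water signals."""
    fat_sample = extract_roi_sample(pair.fat, roi)
    water_sample = extract_roi_sample(pair.water, roi)
    return ImfResult(
        muscle_label=roi.label,
        model_id="DIXON",
        imf_percent=dixon_fat_fraction(fat_sample.values, water_sample.values),
    )


def _config_for(model_id: str, seed: int, n_init: int,
                gmm_config: GmmConfig | None, kmeans_config: KmeansConfig | None):
    kind, k = _MODEL_SPECS[model_id]
    if kind == "gmm":
        base = gmm_config or GmmConfig()
        return replace(base, n_components=k, seed=seed, n_init=n_init)
    base = kmeans_config or KmeansConfig()
    return replace(base, k=k, seed=seed, n_init=n_init)


def run_model(
    sample: IntensitySample,
    model_id: str,
    *,
    seed: int = 0,
    n_init: int = 50,
    gmm_config: GmmConfig | None = None,
    kmeans_config: KmeansConfig | None = None,
) -> tuple[MixtureFit, VoxelClassification, ImfResult]:
    """Fit one thresholding model and return fit, classification and IMF."""
    if model_id not in _MODEL_SPECS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    config = _config_for(model_id, seed, n_init, gmm_config, kmeans_config)
    fit = fit_best(sample, config)
    classification = classify_sample(fit, sample)
    result = imf_t2(classification, muscle_label=sample.muscle_label)
    return fit, classification, result


def quantify_muscle(
    sample: IntensitySample,
    model_id: str,
    *,
    seed: int = 0,
    n_init: int = 50,
    gmm_config: GmmConfig | None = None,
    kmeans_config: KmeansConfig | None = None,
) -> ImfResult:
    """Compose multi-restart fit → classification → T2 IMF for one model.

    Deterministic for a fixed seed: restart streams are derived from
    ``seed`` alone.
    """
    return run_model(
        sample,
        model_id,
        seed=seed,
        n_init=n_init,
        gmm_config=gmm_config,
        kmeans_config=kmeans_config,
    )[2]
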