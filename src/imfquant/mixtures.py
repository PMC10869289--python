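"""Univariate Gaussian-mixture (EM) and K-means fitting with multi-restart.

Intensity histograms inside a muscle ROI are modelled either as a mixture of
2 or 3 Gaussians fitted by expectation-maximisation, or as 2 or 3 clusters
found by Lloyd's algorithm with k-means++ seeding.  Both fits are restarted
``n_init`` times (default 50) from restart-specific RNG streams derived from
a base seed, and the best-scoring fit is kept: maximum log-likelihood for
the GMM, minimum within-cluster sum of squares for K-means.  Components are
always reported in ascending order of mean so the lowest component is the
muscle mode and the highest the fat mode.

In one dimension a "full" covariance matrix reduces to an unconstrained
per-component variance; variances are floored at ``var_floor_frac`` times
the sample variance to keep spiky histograms from producing singular
components.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp

from .core import IntensitySample

__all__ = [
    "GmmConfig",
    "KmeansConfig",
    "MixtureFit",
    "DegenerateFitError",
    "fit_gmm_once",
    "fit_kmeans_once",
    "fit_best",
]

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateFitError(ValueError):
    """A fit collapsed (coincident components, empty sample structure, ...)."""


@dataclass(frozen=True)
class GmmConfig:
    """EM configuration.

    Defaults follow the study protocol: 1000 iterations maximum, tolerance
    0.001 on the change in mean per-sample log-likelihood, 50 restarts,
    k-means-based initialisation.
    """

    n_components: int = 2
    max_iter: int = 1000
    tol: float = 0.001
    n_init: int = 50
    init_method: str = "kmeans"
    var_floor_frac: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if self.init_method != "kmeans":
            raise ValueError("only k-means initialisation is supported")


@dataclass(frozen=True)
class KmeansConfig:
    """Lloyd/k-means++ configuration (defaults mirror :class:`GmmConfig`)."""

    k: int = 2
    max_iter: int = 1000
    tol: float = 0.001
    n_init: int = 50
    init_method: str = "k-means++"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if self.init_method != "k-means++":
            raise ValueError("only k-means++ initialisation is supported")


@dataclass(frozen=True)
class MixtureFit:
    """Fitted component parameters, canonically ordered by ascending mean.

    ``score`` is the total log-likelihood for a GMM and the negative
    within-cluster sum of squares for K-means, so "larger is better" holds
    for both and restart selection is a plain argmax.
    """

    model_kind: str  # "gmm" | "kmeans"
    n_components: int
    means: tuple[float, ...]
    variances: tuple[float, ...] | None
    weights: tuple[float, ...]
    score: float
    converged: bool
    n_iter_used: int
    seed: int | None = None
    loglik_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if len(self.means) != self.n_components:
            raise ValueError("component count mismatch")
        if any(b <= a for a, b in zip(self.means, self.means[1:])):
            raise DegenerateFitError(f"means not strictly ascending: {self.means}")
        if self.model_kind == "gmm":
            w = np.asarray(self.weights)
            if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid mixing weights {self.weights}")

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("loglik_trace")
        return json.dumps(d)


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------

def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding on a 1-D sample.

    Each new center is picked among ``2 + floor(log k)`` candidates drawn
    with probability proportional to the squared distance to the nearest
    chosen center, keeping the candidate that most reduces the potential
    (the common library refinement of the textbook rule).
    """
    n = x.size
    n_trials = 2 + int(math.log(k))
    centers = np.empty(k)
    centers[0] = x[rng.integers(n)]
    d2 = (x - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a chosen center
            centers[j] = x[rng.integers(n)]
            continue
        candidates = x[rng.choice(n, size=n_trials, p=d2 / total)]
        cand_d2 = np.minimum(d2[None, :], (x[None, :] - candidates[:, None]) ** 2)
        best = int(np.argmin(cand_d2.sum(axis=1)))
        centers[j] = candidates[best]
        d2 = cand_d2[best]
    return centers


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Lloyd iterations; returns (centers, assignment, inertia, converged, iters).

    Convergence: relative decrease of within-cluster SS below ``tol``, or an
    unchanged assignment (exact fixed point).  An emptied cluster is
    re-seeded at the point currently farthest from its own center
    (deterministic; ties broken by lowest index).
    """
    k = centers.size
    prev_assign = None
    prev_inertia = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist2 = (x[:, None] - centers[None, :]) ** 2
        assign = np.argmin(dist2, axis=1)
        # resolve empty clusters before the update step
        for j in range(k):
            if not np.any(assign == j):
                far = int(np.argmax(dist2[np.arange(x.size), assign]))
                assign[far] = j
                dist2[far, :] = 0.0  # its contribution is now exactly on-center
        for j in range(k):
            centers[j] = x[assign == j].mean()
        inertia = float(
            np.sum((x - centers[assign]) ** 2)
        )
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            converged = True
            break
        if np.isfinite(prev_inertia) and prev_inertia - inertia <= tol * max(prev_inertia, 1e-300):
            converged = True
            break
        prev_assign = assign
        prev_inertia = inertia
    dist2 = (x[:, None] - centers[None, :]) ** 2
    assign = np.argmin(dist2, axis=1)
    inertia = float(np.sum((x - centers[assign]) ** 2))
    return centers, assign, inertia, converged, n_iter


def fit_kmeans_once(
    sample: IntensitySample, config: KmeansConfig, rng: np.random.Generator
) -> MixtureFit:
    """One k-means++-seeded Lloyd run on the sample."""
    x = sample.values
    k = config.k
    if x.size < k:
        raise ValueError(f"sample of {x.size} voxels cannot support k={k}")
    if np.unique(x).size < k:
        raise DegenerateFitError(
            f"sample has fewer than k={k} distinct values"
        )
    centers = _kmeans_pp_init(x, k, rng)
    centers, assign, inertia, converged, n_iter = _lloyd(
        x, centers, config.max_iter, config.tol
    )
    order = np.argsort(centers)
    centers = centers[order]
    counts = np.array([(assign == j).sum() for j in order], dtype=float)
    if np.any(np.diff(centers) <= 1e-12 * max(1.0, float(np.ptp(x)))):
        raise DegenerateFitError(f"coincident cluster centers {tuple(centers)}")
    return MixtureFit(
        model_kind="kmeans",
        n_components=k,
        means=tuple(float(c) for c in centers),
        variances=None,
        weights=tuple(counts / x.size),
        score=-inertia,
        converged=converged,
        n_iter_used=n_iter,
    )


# ---------------------------------------------------------------------------
# Gaussian mixture / EM
# ---------------------------------------------------------------------------

def _weighted_log_densities(
    x: np.ndarray, means: np.ndarray, variances: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """log(pi_k * N(x | mu_k, sigma_k^2)) as an (n, k) array."""
    return (
        np.log(weights)[None, :]
        - 0.5 * (_LOG_2PI + np.log(variances))[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )


def fit_gmm_once(
    sample: IntensitySample, config: GmmConfig, rng: np.random.Generator
) -> MixtureFit:
    """One EM run on the sample, initialised from a k-means partition.

    The E-step computes per-voxel responsibilities from the weighted
    Gaussian densities; the M-step updates means, variances (floored) and
    mixing proportions.  The mean per-sample log-likelihood is non-decreasing
    across iterations; EM stops when its improvement drops below ``tol``.
    """
    x = sample.values
    k = config.n_components
    if x.size < k:
        raise ValueError(f"sample of {x.size} voxels cannot support {k} components")
    sample_var = float(np.var(x))
    if sample_var <= 0:
        raise DegenerateFitError("zero-variance sample: all intensities equal")
    var_floor = config.var_floor_frac * sample_var

    # k-means initialisation: one Lloyd run seeded by k-means++ from this
    # restart's stream provides the initial partition.
    km = fit_kmeans_once(
        sample,
        KmeansConfig(k=k, max_iter=config.max_iter, tol=config.tol, n_init=1),
        rng,
    )
    means = np.asarray(km.means, dtype=float)
    weights = np.maximum(np.asarray(km.weights, dtype=float), 1.0 / x.size)
    weights = weights / weights.sum()
    dist2 = (x[:, None] - means[None, :]) ** 2
    assign = np.argmin(dist2, axis=1)
    variances = np.array(
        [max(np.var(x[assign == j]) if np.any(assign == j) else 0.0, var_floor)
         for j in range(k)]
    )

    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        # E-step
        wlog = _weighted_log_densities(x, means, variances, weights)
        norm = logsumexp(wlog, axis=1)
        ll = float(np.mean(norm))
        trace.append(ll)
        resp = np.exp(wlog - norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            raise DegenerateFitError("a component lost all responsibility mass")
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = np.maximum(
            (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk, var_floor
        )
        if ll - prev_ll < config.tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll

    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    scale = max(1.0, float(np.ptp(x)))
    if np.any(np.diff(means) <= 1e-10 * scale):
        raise DegenerateFitError(f"components collapsed to identical means {tuple(means)}")
    weights = weights / weights.sum()
    return MixtureFit(
        model_kind="gmm",
        n_components=k,
        means=tuple(float(m) for m in means),
        variances=tuple(float(v) for v in variances),
        weights=tuple(float(w) for w in weights),
        score=float(trace[-1] * x.size),
        converged=converged,
        n_iter_used=n_iter,
        loglik_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# Multi-restart selection
# ---------------------------------------------------------------------------

def fit_best(sample: IntensitySample, config: GmmConfig | KmeansConfig) -> MixtureFit:
    """Best of ``n_init`` restarts, restart *i* seeded with ``seed + i``.

    The restart streams are derived deterministically from the base seed, so
    the returned fit is bit-reproducible for a fixed seed.  Degenerate
    restarts are skipped; if every restart degenerates the errors are
    aggregated.
    """
    if isinstance(config, GmmConfig):
        fit_once, seed = fit_gmm_once, config.seed
    elif isinstance(config, KmeansConfig):
        fit_once, seed = fit_kmeans_once, config.seed
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported config type {type(config)!r}")

    best: MixtureFit | None = None
    errors: list[Exception] = []
    for i in range(config.n_init):
        rng = np.random.default_rng(seed + i)
        try:
            fit = fit_once(sample, config, rng)
        except DegenerateFitError as exc:
            errors.append(exc)
            continue
        if best is None or fit.score > best.score:
            best = fit
    if best is None:
        raise DegenerateFitError(
            f"all {config.n_init} restarts degenerated; first error: {errors[0]}"
        )
    object.__setattr__(best, "seed", int(seed))
    return best
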