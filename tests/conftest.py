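"""Shared fixtures and independent oracles.

The oracles here deliberately use brute force (exhaustive enumeration,
explicit sum-of-squares loops, fine grids) and never call into the package
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from imfquant import IntensitySample


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def kmeans_1d_oracle(x: np.ndarray, k: int) -> tuple[float, list[np.ndarray]]:
    """Globally optimal 1-D k-means by exhaustive contiguous-split search.

    Optimal 1-D clusters are intervals of the sorted sample, so for k=2 all
    n-1 split points are scanned and for k=3 all O(n^2) split pairs.
    Returns (min within-cluster SS, clusters).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def wcss(i: int, j: int) -> float:
        # within-cluster SS of xs[i:j] from prefix sums
        m = j - i
        tot = s1[j] - s1[i]
        return float(s2[j] - s2[i] - tot * tot / m)

    best = (np.inf, None)
    if k == 2:
        for i in range(1, n):
            cost = wcss(0, i) + wcss(i, n)
            if cost < best[0]:
                best = (cost, [xs[:i], xs[i:]])
    elif k == 3:
        for i in range(1, n - 1):
            left = wcss(0, i)
            for j in range(i + 1, n):
                cost = left + wcss(i, j) + wcss(j, n)
                if cost < best[0]:
                    best = (cost, [xs[:i], xs[i:j], xs[j:]])
    else:
        raise ValueError("oracle supports k in {2, 3}")
    return best


def icc31_oracle(table: np.ndarray) -> float:
    """ICC(3,1) from an explicit two-way ANOVA sum-of-squares decomposition."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (table[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (table[:, j].mean() - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (table[i, j] - grand) ** 2
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def rm_anova_oracle(cube: np.ndarray) -> dict:
    """2x2 within-subject ANOVA from the full sum-of-squares decomposition.

    ``cube`` has shape (n, 2, 2): subjects x factor A x factor B.  Each
    effect is tested against its own subject-by-effect interaction with
    (1, n-1) df.  Returns {"A": (F, p), "B": ..., "AB": ...}.
    """
    from scipy import stats

    y = np.asarray(cube, dtype=float)
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a = y.mean(axis=(0, 2))
    b = y.mean(axis=(0, 1))
    ia = y.mean(axis=2)  # (n, 2)
    ib = y.mean(axis=1)  # (n, 2)
    ab = y.mean(axis=0)  # (2, 2)

    ss_a = 2 * n * np.sum((a - grand) ** 2)
    ss_b = 2 * n * np.sum((b - grand) ** 2)
    ss_ab = n * np.sum((ab - a[:, None] - b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((ia - subj[:, None] - a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((ib - subj[:, None] - b[None, :] + grand) ** 2)
    resid = (
        y
        - ia[:, :, None]
        - ib[:, None, :]
        - ab[None, :, :]
        + subj[:, None, None]
        + a[None, :, None]
        + b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    out = {}
    for name, ss_eff, ss_err in (
        ("A", ss_a, ss_as),
        ("B", ss_b, ss_bs),
        ("AB", ss_ab, ss_abs),
    ):
        f = (ss_eff / 1.0) / (ss_err / (n - 1))
        out[name] = (float(f), float(stats.f.sf(f, 1, n - 1)))
    return out


def table_to_cube(table: np.ndarray) -> np.ndarray:
    """(n, 4) model-order table -> (n, 2, 2) cube: A=algorithm, B=components.

    Column order GMM2C, KMEANS2C, GMM3C, KMEANS3C; A index 0 = GMM,
    B index 0 = two components.
    """
    t = np.asarray(table, dtype=float)
    cube = np.empty((t.shape[0], 2, 2))
    cube[:, 0, 0] = t[:, 0]  # GMM, 2C
    cube[:, 1, 0] = t[:, 1]  # KMEANS, 2C
    cube[:, 0, 1] = t[:, 2]  # GMM, 3C
    cube[:, 1, 1] = t[:, 3]  # KMEANS, 3C
    return cube


def gmm_threshold_grid_oracle(fit, lo: float, hi: float, step: float = 0.01) -> float:
    """Posterior-crossing threshold by fine-grid scan of the weighted densities."""
    from imfquant.mixtures import _weighted_log_densities

    xs = np.arange(lo, hi, step)
    wlog = _weighted_log_densities(
        xs, np.asarray(fit.means), np.asarray(fit.variances), np.asarray(fit.weights)
    )
    comp = np.argmax(wlog, axis=1)
    change = np.nonzero(np.diff(comp) > 0)[0]
    assert change.size >= 1
    return float(xs[change[0] + 1])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def bimodal_sample(
    seed: int,
    n: int = 1000,
    mu=(100.0, 400.0),
    sigma=(10.0, 30.0),
    weights=(0.5, 0.5),
    label: str = "LML",
) -> IntensitySample:
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mu), size=n, p=weights)
    values = rng.normal(np.asarray(mu)[comp], np.asarray(sigma)[comp])
    return IntensitySample(values=values, muscle_label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
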