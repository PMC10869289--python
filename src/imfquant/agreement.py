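"""Agreement of thresholding-model IMF with the Dixon reference.

Implements the full evaluation framework: Bland-Altman bias and 95% limits
of agreement, the two-way mixed-effects single-measurement consistency
intraclass correlation ICC(3,1) with the standard reliability bands, mean
absolute error, a 2x2 within-subject (repeated-measures) ANOVA on per-
subject absolute errors with factors algorithm (GMM vs K-means) and
component count (2 vs 3), and post-hoc paired t-tests.

ICC(3,1) follows the Shrout-Fleiss consistency definition

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

with MS_R the between-subject and MS_E the residual mean square of the
subjects x raters two-way ANOVA without interaction; negative values are
returned as computed.  The consistency (not absolute-agreement) form is
used: a fixed offset between a model and the reference does not lower it.

All statistics are deterministic functions of their input tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "EffectResult",
    "RmAnovaResult",
    "bland_altman",
    "icc_3_1",
    "interpret_icc",
    "mae",
    "rm_anova_2x2",
    "paired_t",
    "agreement_report",
    "holm_adjust",
]

#: Multiplier for the 95% limits of agreement.
LOA_MULTIPLIER = 1.96

#: Column order expected by :func:`rm_anova_2x2`.
ANOVA_MODEL_ORDER = ("GMM2C", "KMEANS2C", "GMM3C", "KMEANS3C")


@dataclass(frozen=True)
class PairedSeries:
    """Model and reference IMF values aligned by subject."""

    subject_ids: tuple
    model_values: np.ndarray
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.model_values, dtype=np.float64)
        r = np.asarray(self.reference_values, dtype=np.float64)
        if not (len(self.subject_ids) == m.size == r.size):
            raise ValueError("subject_ids, model and reference must align")
        if m.size < 3:
            raise ValueError(f"need at least 3 paired observations, got {m.size}")
        object.__setattr__(self, "model_values", m)
        object.__setattr__(self, "reference_values", r)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n(self) -> int:
        return self.model_values.size

    @property
    def differences(self) -> np.ndarray:
        """model - reference; negative means the model underestimates."""
        return self.model_values - self.reference_values


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    icc_3_1: float
    icc_category: str
    mae: float

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")
        if self.icc_3_1 > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if self.mae + 1e-12 < abs(self.bias):
            raise ValueError("MAE cannot be smaller than |bias|")


def bland_altman(series: PairedSeries) -> tuple[float, float, float, float]:
    """(bias, SD of differences, LOA lower, LOA upper).

    bias = mean(model - reference); SD uses n-1; LOA = bias +/- 1.96 SD.
    """
    d = series.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of an n x k two-way layout, no interaction."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((table - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_3_1(series: PairedSeries) -> float:
    """Two-way mixed-effects, single-measurement, consistency ICC.

    May be negative (worse-than-chance consistency); returned as computed.
    """
    table = np.column_stack([series.model_values, series.reference_values])
    if np.allclose(table, table.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    ms_r, _, ms_e = _two_way_mean_squares(table)
    k = table.shape[1]
    denom = ms_r + (k - 1) * ms_e
    if denom == 0:
        raise ValueError("zero variance decomposition: ICC undefined")
    return float((ms_r - ms_e) / denom)


def interpret_icc(value: float) -> str:
    """Reliability band: poor < 0.50 <= moderate < 0.75 <= good < 0.90 <= excellent."""
    if value > 1 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.90:
        return "good"
    return "excellent"


def mae(series: PairedSeries) -> float:
    """Mean absolute error of the model against the reference."""
    return float(np.mean(np.abs(series.differences)))


def agreement_report(series: PairedSeries) -> AgreementReport:
    """All accuracy/reliability statistics of one model against the reference."""
    bias, sd, lo, hi = bland_altman(series)
    icc = icc_3_1(series)
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        icc_3_1=icc,
        icc_category=interpret_icc(icc),
        mae=mae(series),
    )


@dataclass(frozen=True)
class EffectResult:
    F: float
    df: tuple[int, int]
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class RmAnovaResult:
    algorithm: EffectResult
    components: EffectResult
    interaction: EffectResult
    sphericity: str = "not applicable (2-level factors)"


def _contrast_effect(scores: np.ndarray) -> EffectResult:
    """F-test of a single within-subject contrast against its own error term.

    For a 2-level factor the repeated-measures F equals the squared paired t
    of the per-subject contrast scores, with (1, n-1) degrees of freedom.
    A zero-variance contrast is flagged degenerate: F = 0 when the effect is
    also zero, infinite when the effect is perfectly constant and nonzero.
    """
    n = scores.size
    mean = float(np.mean(scores))
    var = float(np.var(scores, ddof=1))
    if var == 0.0:
        if mean == 0.0:
            return EffectResult(F=0.0, df=(1, n - 1), p=1.0, degenerate=True)
        return EffectResult(F=np.inf, df=(1, n - 1), p=0.0, degenerate=True)
    f = n * mean**2 / var
    p = float(stats.f.sf(f, 1, n - 1))
    return EffectResult(F=float(f), df=(1, n - 1), p=p)


def rm_anova_2x2(table) -> RmAnovaResult:
    """2x2 within-subject ANOVA on a complete per-subject table.

    ``table`` is an (n_subjects, 4) array or DataFrame whose columns are the
    four models in the order GMM2C, KMEANS2C, GMM3C, KMEANS3C.  Effects:
    algorithm (GMM vs K-means), components (2 vs 3) and their interaction,
    each tested against its subject-by-effect error term with (1, n-1)
    degrees of freedom.  Sphericity is trivially satisfied for 2-level
    within-subject factors and is reported as not applicable.
    """
    if isinstance(table, pd.DataFrame):
        missing = [c for c in ANOVA_MODEL_ORDER if c not in table.columns]
        if missing:
            raise ValueError(f"incomplete table: missing model columns {missing}")
        table = table[list(ANOVA_MODEL_ORDER)].to_numpy(dtype=np.float64)
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[1] != 4:
        raise ValueError(f"expected an (n, 4) table, got shape {table.shape}")
    if table.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(table)):
        raise ValueError("incomplete table: non-finite cells")

    g2, k2, g3, k3 = table.T
    algorithm = _contrast_effect((g2 + g3) / 2 - (k2 + k3) / 2)
    components = _contrast_effect((g3 + k3) / 2 - (g2 + k2) / 2)
    interaction = _contrast_effect((g3 - g2) - (k3 - k2))
    return RmAnovaResult(algorithm=algorithm, components=components,
                         interaction=interaction)


def paired_t(series_a, series_b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p) with df = n - 1.

    t = mean(d) / (sd(d) / sqrt(n)) on the per-subject differences
    d = a - b.  Zero-variance differences raise unless the difference is
    identically zero, in which case (0, n-1, 1) is returned.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    m = float(np.mean(d))
    if sd == 0.0:
        if m == 0.0:
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = m / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
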