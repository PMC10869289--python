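"""Agreement statistics against brute-force and reference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from imfquant import (
    PairedSeries,
    agreement_report,
    bland_altman,
    holm_adjust,
    icc_3_1,
    interpret_icc,
    mae,
    paired_t,
    rm_anova_2x2,
)
from conftest import icc31_oracle, rm_anova_oracle, table_to_cube


def series_of(model, reference):
    model = np.asarray(model, dtype=float)
    return PairedSeries(
        subject_ids=tuple(range(len(model))),
        model_values=model,
        reference_values=np.asarray(reference, dtype=float),
    )


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_bland_altman_identical_series():
    bias, sd, lo, hi = bland_altman(series_of([1, 2, 3], [1, 2, 3]))
    assert (bias, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)


def test_bland_altman_hand_arithmetic():
    bias, sd, lo, hi = bland_altman(series_of([2, 4, 6], [1, 2, 3]))
    assert bias == pytest.approx(2.0)
    assert sd == pytest.approx(1.0)
    assert lo == pytest.approx(2 - 1.96)
    assert hi == pytest.approx(2 + 1.96)


def test_bland_altman_sign_convention_underestimation_is_negative():
    bias, *_ = bland_altman(series_of([10, 20, 30], [15, 25, 35]))
    assert bias == -5.0


def test_loa_nominal_coverage_on_large_normal_sample():
    rng = np.random.default_rng(12345)
    d = rng.normal(-5.0, 5.0, 100_000)
    series = series_of(d, np.zeros_like(d))
    _, _, lo, hi = bland_altman(series)
    coverage = np.mean((d > lo) & (d < hi))
    assert coverage == pytest.approx(0.95, abs=0.005)


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------

def test_icc_consistency_ignores_constant_offset():
    model = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    assert icc_3_1(series_of(model, model + 7.5)) == pytest.approx(1.0)


def test_icc_toy_table_matches_anova_oracle():
    model = [1.0, 2.0, 3.0, 4.0, 5.0]
    reference = [1.5, 2.4, 3.1, 4.6, 4.9]
    got = icc_3_1(series_of(model, reference))
    expected = icc31_oracle(np.column_stack([model, reference]))
    assert got == pytest.approx(expected, rel=1e-12)


def test_icc_negative_when_within_subject_noise_dominates():
    rng = np.random.default_rng(3)
    base = np.full(12, 30.0)
    noise = rng.normal(0, 4, 12)
    # anti-correlated raters: row means are constant, so the between-subject
    # mean square is zero and the residual mean square dominates
    model = base + noise
    reference = base - noise
    got = icc_3_1(series_of(model, reference))
    assert got < 0
    assert got == pytest.approx(
        icc31_oracle(np.column_stack([model, reference])), rel=1e-9
    )


def test_icc_undefined_on_zero_variance():
    with pytest.raises(ValueError, match="undefined"):
        icc_3_1(series_of([5, 5, 5], [5, 5, 5]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), offset=st.floats(-50, 50))
def test_icc_invariant_to_rater_offset(seed, offset):
    rng = np.random.default_rng(seed)
    model = rng.uniform(0, 60, 8)
    reference = model + rng.normal(0, 3, 8)
    a = icc_3_1(series_of(model, reference))
    b = icc_3_1(series_of(model, reference + offset))
    assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


def test_icc_matches_pingouin_reference():
    import pandas as pd

    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    for _ in range(5):
        model = rng.uniform(0, 50, 10)
        reference = model + rng.normal(-3, 5, 10)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "rater": ["model", "reference"] * 10,
            "y": np.column_stack([model, reference]).ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="y").set_index("Type")
        # the consistency/single-measure row is labelled ICC3 or ICC(C,1)
        # depending on the pingouin version
        key = "ICC3" if "ICC3" in table.index else "ICC(C,1)"
        ref_icc = float(table.loc[key, "ICC"])
        got = icc_3_1(series_of(model, reference))
        assert got == pytest.approx(ref_icc, rel=1e-6, abs=1e-9)


@pytest.mark.parametrize(
    "value,category",
    [
        (0.49, "poor"),
        (0.50, "moderate"),
        (0.74999, "moderate"),
        (0.75, "good"),
        (0.77, "good"),
        (0.63, "moderate"),
        (0.90, "excellent"),
        (-0.14, "poor"),
    ],
)
def test_icc_reliability_bands(value, category):
    assert interpret_icc(value) == category


# ---------------------------------------------------------------------------
# MAE
# ---------------------------------------------------------------------------

def test_mae_zero_for_identical_series():
    assert mae(series_of([1, 2, 3], [1, 2, 3])) == 0.0


def test_mae_differs_from_bias():
    s = series_of([0, 4, 2], [2, 2, 2])
    assert mae(s) == pytest.approx(4 / 3)
    assert bland_altman(s)[0] == pytest.approx(0.0)


def test_mae_matches_direct_loop():
    rng = np.random.default_rng(9)
    m, r = rng.uniform(0, 50, 40), rng.uniform(0, 50, 40)
    expected = sum(abs(a - b) for a, b in zip(m, r)) / 40
    assert mae(series_of(m, r)) == pytest.approx(expected, rel=1e-12)


def test_report_mae_dominates_abs_bias():
    rng = np.random.default_rng(4)
    m, r = rng.uniform(0, 50, 20), rng.uniform(0, 50, 20)
    rep = agreement_report(series_of(m, r))
    assert rep.mae >= abs(rep.bias)
    assert rep.loa_lower <= rep.bias <= rep.loa_upper


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def test_rm_anova_null_table_flagged():
    table = np.tile([[3.0, 3.0, 3.0, 3.0]], (5, 1))
    res = rm_anova_2x2(table)
    for eff in (res.algorithm, res.components, res.interaction):
        assert eff.F == 0.0
        assert eff.degenerate


def test_rm_anova_perfectly_constant_effect_flagged():
    rng = np.random.default_rng(0)
    g = rng.uniform(1, 3, (6, 1))
    table = np.hstack([g, g + 5.0, g, g + 5.0])  # K-means = GMM + 5 exactly
    res = rm_anova_2x2(table)
    assert res.algorithm.degenerate
    assert np.isinf(res.algorithm.F)


def test_rm_anova_constant_algorithm_effect_with_noise():
    rng = np.random.default_rng(1)
    g2 = rng.uniform(1, 3, 8)
    table = np.column_stack([g2, g2 + 5.0, g2, g2 + 5.0])
    table = table + rng.normal(0, 0.1, table.shape)
    res = rm_anova_2x2(table)
    assert res.algorithm.p < 0.001
    assert res.interaction.p > 0.05


@pytest.mark.parametrize("seed", range(6))
def test_rm_anova_matches_sum_of_squares_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 15))
    table = rng.uniform(0, 10, (n, 4))
    res = rm_anova_2x2(table)
    oracle = rm_anova_oracle(table_to_cube(table))
    assert res.algorithm.F == pytest.approx(oracle["A"][0], rel=1e-9)
    assert res.components.F == pytest.approx(oracle["B"][0], rel=1e-9)
    assert res.interaction.F == pytest.approx(oracle["AB"][0], rel=1e-9)
    assert res.algorithm.p == pytest.approx(oracle["A"][1], rel=1e-9)
    assert res.algorithm.df == (1, n - 1)


def test_rm_anova_matches_statsmodels():
    import pandas as pd

    pytest.importorskip("statsmodels")
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(77)
    table = rng.uniform(0, 10, (10, 4))
    res = rm_anova_2x2(table)
    long = []
    for i in range(10):
        for j, (alg, comp) in enumerate(
            [("gmm", "c2"), ("km", "c2"), ("gmm", "c3"), ("km", "c3")]
        ):
            long.append({"subject": i, "alg": alg, "comp": comp,
                         "y": table[i, j]})
    fitted = AnovaRM(pd.DataFrame(long), "y", "subject",
                     within=["alg", "comp"]).fit()
    sm = fitted.anova_table["F Value"]
    assert res.algorithm.F == pytest.approx(sm["alg"], rel=1e-8)
    assert res.components.F == pytest.approx(sm["comp"], rel=1e-8)
    assert res.interaction.F == pytest.approx(sm["alg:comp"], rel=1e-8)


def test_rm_anova_rejects_incomplete_tables():
    with pytest.raises(ValueError):
        rm_anova_2x2(np.ones((2, 4)))
    bad = np.ones((5, 4))
    bad[0, 2] = np.nan
    with pytest.raises(ValueError, match="incomplete"):
        rm_anova_2x2(bad)


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_identical_series_is_null():
    t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, df, p) == (0.0, 2, 1.0)


def test_paired_t_closed_form_and_scipy_agreement():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 30, 12)
    b = a + rng.normal(1.0, 2.0, 12)
    t, df, p = paired_t(a, b)
    d = a - b
    t_closed = d.mean() / (d.std(ddof=1) / np.sqrt(12))
    assert t == pytest.approx(t_closed, rel=1e-12)
    ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(ref.statistic, rel=1e-10)
    assert p == pytest.approx(ref.pvalue, rel=1e-10)
    assert df == 11


def test_paired_t_zero_variance_nonzero_difference_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def test_holm_adjustment_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.6]
    adj = holm_adjust(p)
    import statsmodels.stats.multitest as mt

    expected = mt.multipletests(p, method="holm")[1]
    np.testing.assert_allclose(adj, expected, rtol=1e-12)
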