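"""ANOVA, univariate screening and the stratum-clustered mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flairstrata import (compare_models, fit_lmm, simulate_stratum_table,
                         strata_anova, univariate_screen)


def _table_from_groups(groups):
    rows = []
    for k, vals in enumerate(groups, start=1):
        for i, v in enumerate(vals):
            rows.append({"subject_id": f"S{i}", "stratum": str(k),
                         "nawm_m": v, "lka_volume_cm3": 1.0,
                         "lka_quartile": 1, "age_decades": 6.8,
                         "hypertension": 0})
    return pd.DataFrame(rows)


def test_two_group_anova_equals_squared_t(rng):
    a, b = rng.normal(1.1, 0.05, 30), rng.normal(1.15, 0.05, 30)
    f, p = strata_anova(_table_from_groups([a, b]))
    t, pt = sps.ttest_ind(a, b)
    assert f == pytest.approx(t ** 2, rel=1e-10)
    assert p == pytest.approx(pt, rel=1e-10)


def test_anova_identical_group_means(rng):
    base = rng.normal(0, 1, 40)
    base -= base.mean()  # exactly zero-mean deviations
    groups = [1.0 + base, 1.0 + np.flip(base), 1.0 - base]  # equal means
    f, _ = strata_anova(_table_from_groups(groups))
    assert f == pytest.approx(0.0, abs=1e-10)
    # permutation oracle: virtually every relabelling gives a larger F
    pooled = np.concatenate(groups)
    ge = 0
    n_perm = 200
    for s in range(n_perm):
        perm = np.random.default_rng(s).permutation(pooled)
        fp, _ = strata_anova(_table_from_groups(np.split(perm, 3)))
        ge += fp >= f
    assert ge / n_perm > 0.95


def test_anova_needs_enough_groups():
    with pytest.raises(ValueError, match=">= 2 strata"):
        strata_anova(_table_from_groups([[1.0, 1.1]]))


def _subject_df(n, rng, y=None):
    return pd.DataFrame({
        "nawm_m": rng.normal(1.15, 0.06, n) if y is None else y,
        "age": rng.normal(68, 16, n),
        "hypertension": rng.integers(0, 2, n),
        "always_one": np.ones(n, dtype=int),
    })


def test_univariate_pearson_on_linear_normal_data(rng):
    df = _subject_df(60, rng)
    df["nawm_m"] = 1.0 + 0.01 * df["age"]  # exactly linear
    res = univariate_screen(df, {"age": "quantitative"})
    row = res.iloc[0]
    assert row["test"] == "pearson"
    assert row["statistic"] == pytest.approx(1.0)


def test_univariate_spearman_on_monotone_nonlinear(rng):
    df = _subject_df(60, rng)
    df["expo"] = np.exp(df["nawm_m"] * 40)  # heavily skewed covariate
    res = univariate_screen(df, {"expo": "quantitative"})
    row = res.iloc[0]
    assert row["test"] == "spearman"
    assert row["statistic"] == pytest.approx(1.0)
    # Pearson on the same data would be < 1
    assert sps.pearsonr(df["expo"], df["nawm_m"]).statistic < 0.999


def test_univariate_binary_and_single_level(rng):
    df = _subject_df(50, rng)
    res = univariate_screen(df, {"hypertension": "binary",
                                 "always_one": "binary"})
    by = res.set_index("covariate")
    assert by.loc["hypertension", "test"] in ("t", "wilcoxon")
    assert by.loc["always_one", "test"] == "skipped"
    assert np.isnan(by.loc["always_one", "p"])


def test_univariate_null_p_values_are_uniform():
    """Group labels independent of the outcome give uniform p-values."""
    rng = np.random.default_rng(99)
    ps = []
    for _ in range(300):
        df = _subject_df(40, rng)
        res = univariate_screen(df, {"hypertension": "binary"})
        ps.append(res["p"].iloc[0])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_lmm_exact_recovery_with_zero_noise():
    """Zero random-effect variance and zero residual noise: the fixed
    effects are recovered exactly (flagged as a boundary fit)."""
    truth = dict(intercept=1.0, quartile_effect=0.025,
                 age_effect_per_decade=0.011, hypertension_effect=0.006)
    t = simulate_stratum_table(
        40, stratum_intercepts=np.zeros(5), stratum_slopes=np.zeros(5),
        residual_sd=0.0, seed=3, **truth)
    r = fit_lmm(t, random_slopes=False, method="REML")
    assert r.boundary_fit
    assert r.fixed_effects["intercept"].estimate == pytest.approx(1.0, abs=1e-6)
    assert r.fixed_effects["lka_quartile"].estimate == pytest.approx(
        0.025, abs=1e-6)
    assert r.fixed_effects["age_decades"].estimate == pytest.approx(
        0.011, abs=1e-6)
    assert r.fixed_effects["hypertension"].estimate == pytest.approx(
        0.006, abs=1e-6)


def test_lmm_wald_ci_and_aic_definitions():
    t = simulate_stratum_table(60, seed=4)
    r = fit_lmm(t, random_slopes=False, method="ML")
    fe = r.fixed_effects["lka_quartile"]
    assert fe.ci_low == pytest.approx(fe.estimate - 1.96 * fe.se, abs=1e-12)
    assert fe.ci_high == pytest.approx(fe.estimate + 1.96 * fe.se, abs=1e-12)
    # AIC = 2k - 2 logLik with k = 4 fixed + 1 RE variance + 1 residual
    assert r.aic == pytest.approx(2 * 6 - 2 * r.log_likelihood, abs=1e-9)
    rs = fit_lmm(t, random_slopes=True, method="ML")
    assert rs.aic == pytest.approx(2 * 8 - 2 * rs.log_likelihood, abs=1e-9)


def test_random_slopes_and_intercepts_agree_on_homogeneous_data():
    """With no real slope heterogeneity the two models give fixed effects
    within one standard error of each other."""
    t = simulate_stratum_table(100, stratum_slope_sd=0.0, seed=5)
    ri = fit_lmm(t, random_slopes=False, method="REML")
    rs = fit_lmm(t, random_slopes=True, method="REML")
    a, b = ri.fixed_effects["lka_quartile"], rs.fixed_effects["lka_quartile"]
    assert abs(a.estimate - b.estimate) <= max(a.se, b.se)


def test_conditional_mode_slopes_rank_correlate_with_truth():
    """Per-stratum injected slope pattern is recovered in rank order."""
    truth = np.array([0.014, 0.024, 0.027, 0.028, 0.029]) - 0.0244
    hits = 0
    for rep in range(25):
        t = simulate_stratum_table(100, quartile_effect=0.0244,
                                   stratum_slopes=truth,
                                   residual_sd=0.002, seed=1000 + rep)
        r = fit_lmm(t, random_slopes=True, method="REML")
        slopes = [r.per_stratum_slopes()[str(k)] for k in range(1, 6)]
        rho = sps.spearmanr(slopes, truth).statistic
        hits += (rho > 1.0 - 1e-9)  # perfect rank agreement
    assert hits >= 24


def test_ml_loglik_nesting():
    t = simulate_stratum_table(80, stratum_slope_sd=0.005, seed=6)
    ri = fit_lmm(t, random_slopes=False, method="ML")
    rs = fit_lmm(t, random_slopes=True, method="ML")
    assert rs.log_likelihood >= ri.log_likelihood - 1e-6


def test_fixed_effects_invariant_to_stratum_relabeling():
    t = simulate_stratum_table(60, seed=7)
    perm = {"1": "5", "2": "3", "3": "1", "4": "2", "5": "4"}
    t2 = t.assign(stratum=t["stratum"].map(perm))
    a = fit_lmm(t, random_slopes=False, method="REML")
    b = fit_lmm(t2, random_slopes=False, method="REML")
    for term in a.fixed_effects:
        assert a.fixed_effects[term].estimate == pytest.approx(
            b.fixed_effects[term].estimate, abs=1e-8)


def test_compare_models_identical_table_is_consistent():
    t = simulate_stratum_table(80, seed=8)
    c1 = compare_models(t)
    c2 = compare_models(t)
    assert c1.aic_intercepts == pytest.approx(c2.aic_intercepts, abs=1e-9)
    assert c1.lrt_statistic == pytest.approx(c2.lrt_statistic, abs=1e-9)
    assert c1.lrt_statistic >= 0.0
    assert c1.lrt_df == 2
    assert 0.0 <= c1.lrt_p <= 1.0


def test_full_rows_are_excluded_from_models():
    t = simulate_stratum_table(40, seed=9)
    extra = t[t["stratum"] == "1"].assign(stratum="full",
                                          nawm_m=lambda d: d["nawm_m"] + 10)
    r1 = fit_lmm(t, random_slopes=False, method="ML")
    r2 = fit_lmm(pd.concat([t, extra]), random_slopes=False, method="ML")
    assert r1.fixed_effects["lka_quartile"].estimate == pytest.approx(
        r2.fixed_effects["lka_quartile"].estimate, abs=1e-12)
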