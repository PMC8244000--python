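"""Mixed model, model selection, composites, lasso, mediation, subgroups."""

import numpy as np
import pandas as pd
import pytest

from readrisk.cohort import Study2Config, cascade_config, generate_study2_cohort
from readrisk.study2 import (
    additive_model_selection,
    build_composites,
    fit_median_rt_model,
    fit_parameter_model,
    lasso_cv,
    mean_drift,
    mediation_analysis,
    parameter_correlation_structure,
    subgroup_analysis,
    zscore,
)


# ---------------------------------------------------------------------------
# median RT mixed model


def _mixed_model_data(rng, n_subjects=100, b_coh=-0.17, b_read=-0.006, b_age=-0.05,
                      subj_sd=0.15, noise_sd=0.05):
    """Directly synthesize per-subject-per-coherence medians from the LMM."""
    rows = []
    for s in range(n_subjects):
        age = rng.uniform(8, 12)
        reading = rng.normal(100, 15)
        intercept = 1.0 + rng.normal(0, subj_sd)
        for coh in (6, 12, 24, 48):
            rows.append({
                "subject_id": f"s{s}", "coherence": coh, "age": age, "reading": reading,
                "median_rt": intercept + b_coh * np.log(coh) + b_read * reading
                + b_age * age + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


def test_mixed_model_recovers_planted_effects(rng):
    df = _mixed_model_data(rng)
    out = fit_median_rt_model(df)
    t = out["table"].table.set_index("term")
    # planted slopes on the raw scale; model works on z-scores, so convert
    sd_coh = df["coherence"].std(ddof=0)
    # coherence entered linearly while the truth is log-linear: check sign
    assert t.loc["z_coherence", "beta"] < 0
    b_read = t.loc["z_reading", "beta"]
    expected = -0.006 * df["reading"].std(ddof=0) / df["median_rt"].std(ddof=0) \
        * df["median_rt"].std(ddof=0)
    assert abs(b_read - (-0.006 * df["reading"].std(ddof=0))) < 3 * t.loc["z_reading", "se"] + 0.02
    assert out["random_intercept_var"] > 0.01


def test_mixed_model_degenerate_random_effect(rng):
    df = _mixed_model_data(rng, subj_sd=0.0, noise_sd=0.02)
    out = fit_median_rt_model(df)
    assert out["singular"] or out["random_intercept_var"] < 1e-3


def test_mixed_model_requires_multiple_coherences(rng):
    df = _mixed_model_data(rng, n_subjects=5)
    with pytest.raises(ValueError, match="coherence"):
        fit_median_rt_model(df[df["coherence"] == 6])


def test_mixed_model_negative_coherence_effect_on_ddm_cohort():
    """On a DDM-generated cohort, higher coherence -> faster RT."""
    from readrisk.preprocess import cohort_rt_summaries, drop_excluded_coherence

    coh = generate_study2_cohort(Study2Config(n_subjects=25, trials_per_coherence=40),
                                 seed=77)
    trials = drop_excluded_coherence(coh.trials)
    med = cohort_rt_summaries(trials)
    med = med.merge(coh.scores[["subject_id", "age"]], on="subject_id")
    reading = coh.scores.set_index("subject_id")[["wj_brs", "towre_index"]].mean(axis=1)
    med["reading"] = reading.loc[med["subject_id"]].to_numpy()
    out = fit_median_rt_model(med)
    t = out["table"].table.set_index("term")
    assert t.loc["z_coherence", "beta"] < 0
    assert t.loc["z_coherence", "p"] < 1e-6


# ---------------------------------------------------------------------------
# per-parameter models


def test_parameter_model_recovers_planted_szeffect(merged_study2):
    tab = fit_parameter_model(merged_study2.rename(columns={"s_z": "s_z"}).assign(
        s_z=lambda d: d["d_comp"]), "s_z")
    # d_comp carries the planted decision-variability effect on reading
    terms = set(tab.table["term"])
    assert "s_z" in terms
    assert tab.partial_r2["s_z"] > 0.01


def test_parameter_model_null_predictor_often_dropped(study2_cohort_noim, rng):
    dropped = 0
    reps = 30
    coh = study2_cohort_noim
    base = coh.scores.copy()
    base["reading"] = base[["wj_brs", "towre_index"]].mean(axis=1)
    for i in range(reps):
        df = base.sample(n=106, random_state=i).copy()
        df["noise_param"] = rng.standard_normal(len(df))
        tab = fit_parameter_model(df, "noise_param")
        if "noise_param" not in set(tab.table["term"]):
            dropped += 1
    # AIC admits a pure-noise term with prob ~ P(chi2_1 > 2) ~ 0.157
    assert dropped / reps > 0.6


def test_parameter_model_refuses_small_n(merged_study2):
    with pytest.raises(ValueError, match=">= 20"):
        fit_parameter_model(merged_study2.head(10), "a")


# ---------------------------------------------------------------------------
# correlation structure


def test_holm_sidak_adjustment_formula(rng):
    """Smallest of m=2 p-values (0.01, 0.04) adjusts to 1-(1-0.01)^2."""
    n = 300
    x = rng.standard_normal(n)
    # build three columns whose pairwise p-values we then feed through the
    # machinery indirectly: easier to check the formula on the output mask
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests([0.01, 0.04], method="holm-sidak")
    assert p_adj[0] == pytest.approx(1 - (1 - 0.01) ** 2)


def test_correlation_structure_null_no_significant(rng):
    X = pd.DataFrame(rng.standard_normal((500, 6)),
                     columns=[f"p{i}" for i in range(6)])
    out = parameter_correlation_structure(X)
    assert out["significant"].to_numpy().sum() == 0


def test_correlation_structure_planted_blocks(rng):
    """A planted 3-block correlation structure is recovered at k=3."""
    n = 400
    blocks = {}
    cols = {}
    for b, names in enumerate((["a1", "a2", "a3"], ["b1", "b2"], ["c1", "c2"])):
        f = rng.standard_normal(n)
        for name in names:
            cols[name] = 0.85 * f + np.sqrt(1 - 0.85**2) * rng.standard_normal(n)
            blocks[name] = b
    X = pd.DataFrame(cols)
    out = parameter_correlation_structure(X, k_clusters=3)
    lab = out["clusters"]
    for names in (["a1", "a2", "a3"], ["b1", "b2"], ["c1", "c2"]):
        assert len(set(lab[names])) == 1
    assert lab.nunique() == 3
    # within-block correlations flagged significant
    assert out["significant"].loc["a1", "a2"]


def test_correlation_structure_constant_column(rng):
    X = pd.DataFrame(rng.standard_normal((50, 3)), columns=["x", "y", "z"])
    X["z"] = 1.0
    with pytest.raises(ValueError, match="z"):
        parameter_correlation_structure(X)


# ---------------------------------------------------------------------------
# composites


def test_composites_perfectly_correlated_constituents(rng):
    base = rng.standard_normal(200)
    fits = pd.DataFrame({
        "v6": base, "v12": 2 * base + 1, "v24": 0.5 * base, "v48": base - 3,
        "s_v": 3 * base, "s_t": rng.standard_normal(200),
        "t_nd": rng.standard_normal(200), "s_z": rng.standard_normal(200),
        "a": rng.standard_normal(200),
    })
    comp = build_composites(fits)
    assert comp.attrs["pc1_share"]["v_comp"] == pytest.approx(1.0)
    np.testing.assert_allclose(comp["v_comp"], zscore(base), atol=1e-8)


def test_composites_independent_constituents_share(rng):
    n = 10000
    fits = pd.DataFrame({c: rng.standard_normal(n)
                         for c in ("v6", "v12", "v24", "v48", "s_v", "s_t",
                                   "t_nd", "s_z", "a")})
    comp = build_composites(fits)
    # PC1 share of k independent variables ~ 1/k (slightly above, by chance)
    assert abs(comp.attrs["pc1_share"]["v_comp"] - 1 / 5) < 0.05
    assert abs(comp.attrs["pc1_share"]["d_comp"] - 1 / 3) < 0.06


def test_composites_orientation_and_unit_variance(study2_cohort_noim):
    comp = build_composites(study2_cohort_noim.true_params)
    fits = study2_cohort_noim.true_params
    for name, cols in (("v_comp", ["v6", "v12", "v24", "v48", "s_v"]),
                       ("d_comp", ["s_t", "t_nd", "s_z"])):
        assert comp[name].std(ddof=0) == pytest.approx(1.0)
        assert comp[name].mean() == pytest.approx(0.0, abs=1e-10)
        mean_z = np.column_stack([zscore(fits[c]) for c in cols]).mean(axis=1)
        assert np.corrcoef(comp[name], mean_z)[0, 1] > 0


def test_composites_missing_column(rng):
    with pytest.raises(ValueError, match="v48"):
        build_composites(pd.DataFrame({"v6": [1.0, 2.0], "v12": [1.0, 2.0],
                                       "v24": [1.0, 2.0]}))


# ---------------------------------------------------------------------------
# additive model selection


def test_additive_model_f_nonnegative_and_nested_loglik(merged_study2):
    out = additive_model_selection(merged_study2)
    assert out["f_test"]["F"] >= 0
    # larger model's loglik >= smaller model's
    k_full = len(out["full"].table)
    k_red = len(out["reduced"].table)
    ll_full = k_full - out["full"].aic / 2
    ll_red = k_red - out["reduced"].aic / 2
    assert ll_full >= ll_red - 1e-9


def test_additive_model_retains_ddm_block_when_planted(merged_study2):
    out = additive_model_selection(merged_study2)
    assert out["ddm_block_retained"]
    assert out["f_test"]["p"] < 0.05


def test_additive_model_drops_ddm_under_cascade():
    coh = generate_study2_cohort(cascade_config(n_subjects=400), seed=21, simulate=False)
    comp = build_composites(coh.true_params)
    merged = comp.merge(coh.scores, on="subject_id")
    merged["reading"] = merged[["wj_brs", "towre_index"]].mean(axis=1)
    out = additive_model_selection(merged)
    assert out["f_test"]["p"] > 0.05


def test_additive_model_rank_deficiency(merged_study2):
    df = merged_study2.copy()
    df["ctopp_ran"] = df["ctopp_pa"]
    with pytest.raises(ValueError, match="rank"):
        additive_model_selection(df)


# ---------------------------------------------------------------------------
# lasso


def test_lasso_penalty_extremes(rng):
    n, p = 200, 5
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=list("abcde"))
    y = 0.7 * X["a"] - 0.4 * X["b"] + 0.1 * rng.standard_normal(n)
    out = lasso_cv(X, y, seed=0)
    import statsmodels.api as sm
    from sklearn.linear_model import Lasso

    Xz = np.column_stack([zscore(X[c]) for c in X.columns])
    # huge penalty kills all slopes
    all_zero = Lasso(alpha=1e6).fit(Xz, zscore(y)).coef_
    assert np.allclose(all_zero, 0)
    # tiny penalty approaches OLS
    near_ols = Lasso(alpha=1e-8).fit(Xz, zscore(y)).coef_
    ols = sm.OLS(zscore(y), Xz).fit().params
    np.testing.assert_allclose(near_ols, ols, atol=1e-4)
    # CV-selected model keeps the true support
    assert {"a", "b"} <= set(out["support"])


def test_lasso_support_recovery(rng):
    hits = 0
    reps = 15
    for i in range(reps):
        X = pd.DataFrame(rng.standard_normal((500, 8)),
                         columns=[f"x{j}" for j in range(8)])
        y = 0.5 * X["x0"] - 0.5 * X["x3"] + 0.4 * X["x6"] + rng.standard_normal(500)
        out = lasso_cv(X, y, seed=i)
        if {"x0", "x3", "x6"} <= set(out["support"]):
            hits += 1
    assert hits / reps >= 0.9


def test_lasso_rejects_too_few_rows(rng):
    X = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
    with pytest.raises(ValueError, match="folds"):
        lasso_cv(X, rng.standard_normal(5))


# ---------------------------------------------------------------------------
# mediation


def _mediation_data(rng, n=300, a=0.0, b=0.0, direct=0.0):
    x = rng.standard_normal(n)
    m = a * x + rng.standard_normal(n) * np.sqrt(max(1 - a**2, 0.05))
    y = direct * x + b * m + rng.standard_normal(n) * 0.6
    return pd.DataFrame({"x": x, "m": m, "y": y})


def test_mediation_total_is_direct_plus_indirect(rng):
    df = _mediation_data(rng, a=0.6, b=0.5, direct=0.3)
    out = mediation_analysis(df, "x", "m", "y", n_boot=200, seed=0)
    import statsmodels.api as sm

    total_fit = sm.OLS(zscore(df["y"]), sm.add_constant(zscore(df["x"]))).fit()
    assert out["total"] == pytest.approx(float(total_fit.params[1]), abs=1e-8)


def test_mediation_direct_only_null_indirect(rng):
    df = _mediation_data(rng, a=0.0, b=0.0, direct=0.5)
    out = mediation_analysis(df, "x", "m", "y", n_boot=500, seed=1)
    lo, hi = out["indirect_ci"]
    assert lo <= 0 <= hi


def test_mediation_full_mediation_detected(rng):
    detected = 0
    reps = 10
    for i in range(reps):
        df = _mediation_data(rng, a=0.7, b=0.6, direct=0.0)
        out = mediation_analysis(df, "x", "m", "y", n_boot=400, seed=i)
        ind_lo, ind_hi = out["indirect_ci"]
        dir_lo, dir_hi = out["direct_ci"]
        if (ind_lo > 0 or ind_hi < 0) and (dir_lo <= 0 <= dir_hi):
            detected += 1
    assert detected / reps >= 0.8


def test_mediation_zero_variance_mediator(rng):
    df = _mediation_data(rng)
    df["m"] = 1.0
    with pytest.raises(ValueError, match="zero-variance"):
        mediation_analysis(df, "x", "m", "y", n_boot=10)


# ---------------------------------------------------------------------------
# subgroup analysis


def test_subgroup_cutoff_below_minimum_equals_full_sample(merged_study2):
    full = subgroup_analysis(merged_study2, "ctopp_pa",
                             merged_study2["ctopp_pa"].min() - 1)
    assert full["n"] == len(merged_study2)


def test_subgroup_too_small(merged_study2):
    with pytest.raises(ValueError, match="too small"):
        subgroup_analysis(merged_study2, "ctopp_pa", 1e9)


def test_subgroup_planted_stratum_effect(rng):
    """A drift-reading link planted only in the high-PA stratum is found
    there and not in the complementary stratum."""
    hits = 0
    reps = 10
    for i in range(reps):
        local = np.random.default_rng(1000 + i)
        n = 300
        pa = local.normal(100, 15, n)
        drift = local.standard_normal((n, 4)) * 0.3 + local.standard_normal(n)[:, None]
        fits = pd.DataFrame(drift, columns=["v6", "v12", "v24", "v48"])
        high = pa >= 100
        reading = np.where(high, 0.6 * zscore(fits.mean(axis=1)), 0.0) \
            + 0.5 * local.standard_normal(n)
        df = pd.DataFrame({
            "ctopp_pa": pa, "ctopp_ran": local.normal(100, 15, n),
            "nonverbal_iq": local.normal(100, 15, n),
            "reading": reading, "mean_drift": mean_drift(fits),
        })
        hi = subgroup_analysis(df, "ctopp_pa", 100)
        lo = subgroup_analysis(df[df["ctopp_pa"] < 100].assign(), "ctopp_pa", 0)
        if hi["p"] < 0.05 and lo["p"] > 0.05:
            hits += 1
    assert hits / reps >= 0.8
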