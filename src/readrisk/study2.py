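"""Statistical modelling of reading skill from DDM parameters and phonology.

Covers the full modelling sequence for the psychophysics study: a mixed
model of median RT, per-parameter models of reading skill with all-subsets
AIC selection, the parameter correlation/cluster structure, principal-
component composites of the sensory and non-sensory parameters, the additive
model of reading skill with a nested F-test against a phonology-only model,
lasso regression, product-of-coefficients mediation, and PA-stratified
subgroup analyses.

All continuous variables are z-scored before modelling, so coefficients are
on the standardized scale. Model selection is exhaustive all-subsets by AIC
with ties broken toward fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .study1 import CoefficientTable


def zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=0)


def _ols_table(res, name: str, partial_r2: dict | None = None) -> CoefficientTable:
    tab = pd.DataFrame({
        "term": res.params.index,
        "beta": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "p": res.pvalues.to_numpy(),
    }).reset_index(drop=True)
    return CoefficientTable(table=tab, aic=float(res.aic), bic=float(res.bic),
                            partial_r2=partial_r2 or {}, model_name=name)


# ---------------------------------------------------------------------------
# median RT mixed model


def fit_median_rt_model(medians: pd.DataFrame) -> dict:
    """Linear mixed model of per-subject-per-coherence median RT.

    Fixed effects for z-scored coherence, age and reading skill; random
    intercept per subject, fit by REML. Expects columns subject_id,
    coherence, median_rt, age, reading. Falls back to OLS with a warning
    flag when the random-intercept variance degenerates.
    """
    df = medians.copy()
    if df.groupby("subject_id")["coherence"].nunique().min() < 2:
        raise ValueError("each subject needs >= 2 coherence levels")
    for col in ("coherence", "age", "reading"):
        df[f"z_{col}"] = zscore(df[col])
    fixed = "median_rt ~ z_coherence + z_age + z_reading"
    model = smf.mixedlm(fixed, df, groups=df["subject_id"])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    re_var = float(res.cov_re.iloc[0, 0])
    singular = not np.isfinite(re_var) or re_var < 1e-8
    if singular:
        ols = smf.ols(fixed, data=df).fit()
        return {"table": _ols_table(ols, "median RT (OLS fallback)"),
                "random_intercept_var": 0.0, "singular": True}
    tab = pd.DataFrame({
        "term": res.fe_params.index,
        "beta": res.fe_params.to_numpy(),
        "se": res.bse.loc[res.fe_params.index].to_numpy(),
        "p": res.pvalues.loc[res.fe_params.index].to_numpy(),
    }).reset_index(drop=True)
    return {
        "table": CoefficientTable(table=tab, aic=float(res.aic), bic=float(res.bic),
                                  model_name="median RT mixed model"),
        "random_intercept_var": re_var,
        "singular": False,
    }


# ---------------------------------------------------------------------------
# all-subsets AIC selection


def _all_subsets_ols(y: np.ndarray, X: pd.DataFrame, candidates: list[str]):
    """Best-AIC OLS over all subsets of ``candidates``; ties -> fewer terms."""
    best = None
    n = len(y)
    for k in range(len(candidates) + 1):
        for subset in combinations(candidates, k):
            cols = list(subset)
            design = sm.add_constant(X[cols]) if cols else pd.DataFrame(
                {"const": np.ones(n)}, index=X.index)
            res = sm.OLS(y, design).fit()
            key = (round(res.aic, 10), len(cols))
            if best is None or key < best[0]:
                best = (key, subset, res)
    return best[1], best[2]


def fit_parameter_model(
    scores: pd.DataFrame,
    parameter: str,
    outcome: str = "reading",
    covariates: tuple = ("age", "nonverbal_iq", "adhd"),
) -> CoefficientTable:
    """Model reading skill from one DDM parameter plus covariates.

    All-subsets AIC selection over the focal parameter and the covariates;
    continuous variables are z-scored. The focal parameter's partial r^2
    (squared semipartial within the selected model) is reported when the
    parameter is retained.
    """
    if len(scores) < 20:
        raise ValueError(f"need >= 20 subjects, got {len(scores)}")
    df = scores.copy()
    y = zscore(df[outcome])
    X = pd.DataFrame(index=df.index)
    for col in (parameter, *covariates):
        vals = df[col].astype(float)
        X[col] = vals if set(np.unique(vals)) <= {0.0, 1.0} else zscore(vals)
    selected, res = _all_subsets_ols(y, X, [parameter, *covariates])
    partial = {}
    if parameter in selected:
        reduced_cols = [c for c in selected if c != parameter]
        reduced = sm.OLS(y, sm.add_constant(X[reduced_cols]) if reduced_cols
                         else np.ones((len(y), 1))).fit()
        denom = reduced.ssr
        partial[parameter] = float((reduced.ssr - res.ssr) / denom) if denom > 0 else 0.0
    return _ols_table(res, f"{outcome} ~ {parameter} (AIC-selected)", partial)


# ---------------------------------------------------------------------------
# correlation structure


def parameter_correlation_structure(
    params: pd.DataFrame,
    k_clusters: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Pearson correlations, Holm-Sidak significance mask, Ward clusters.

    Clustering uses distance 1 - r so positively correlated blocks merge
    first; the dendrogram is cut at ``k_clusters``.
    """
    if params.shape[1] < 3 or params.shape[0] < 10:
        raise ValueError("need >= 3 parameters and >= 10 subjects")
    constant = params.columns[params.std(ddof=0) < 1e-12]
    if len(constant):
        raise ValueError(f"constant parameter column(s): {list(constant)}")
    cols = list(params.columns)
    R = params.corr()
    pvals = []
    pairs = []
    for i, j in combinations(range(len(cols)), 2):
        r, p = stats.pearsonr(params.iloc[:, i], params.iloc[:, j])
        pvals.append(p)
        pairs.append((i, j))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm-sidak")
    mask = pd.DataFrame(False, index=cols, columns=cols)
    p_adj_mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    for (i, j), rej, pa in zip(pairs, reject, p_adj):
        mask.iloc[i, j] = mask.iloc[j, i] = bool(rej)
        p_adj_mat.iloc[i, j] = p_adj_mat.iloc[j, i] = pa
    dist = 1.0 - R.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=k_clusters, criterion="maxclust")
    return {
        "correlations": R,
        "significant": mask,
        "p_adjusted": p_adj_mat,
        "linkage": Z,
        "clusters": pd.Series(labels, index=cols, name="cluster"),
    }


# ---------------------------------------------------------------------------
# composites


V_COMP_VARS = ("v6", "v12", "v24", "v48", "s_v")
D_COMP_VARS = ("s_t", "t_nd", "s_z")


def build_composites(fits: pd.DataFrame) -> pd.DataFrame:
    """Sensory and non-sensory composites from per-subject parameter fits.

    v_comp is the first principal component of the four drift rates and s_v;
    d_comp the first principal component of s_t, t_nd and s_z. Both are
    unit-variance and sign-oriented to correlate positively with the mean of
    their z-scored constituents; ``a`` passes through z-scored. PC1
    explained-variance shares are stored in ``attrs``.
    """
    for col in (*V_COMP_VARS, *D_COMP_VARS, "a"):
        if col not in fits.columns:
            raise ValueError(f"missing parameter column {col!r}")
    out = pd.DataFrame(index=fits.index)
    shares = {}
    for name, cols in (("v_comp", V_COMP_VARS), ("d_comp", D_COMP_VARS)):
        Z = np.column_stack([zscore(fits[c]) for c in cols])
        pca = PCA(n_components=1)
        pc1 = pca.fit_transform(Z)[:, 0]
        pc1 = pc1 / pc1.std(ddof=0)
        orient = np.corrcoef(pc1, Z.mean(axis=1))[0, 1]
        if orient < 0:
            pc1 = -pc1
        out[name] = pc1
        shares[name] = float(pca.explained_variance_ratio_[0])
    out["a"] = zscore(fits["a"])
    if "subject_id" in fits.columns:
        out.insert(0, "subject_id", fits["subject_id"].to_numpy())
    out.attrs["pc1_share"] = shares
    return out


# ---------------------------------------------------------------------------
# additive model of reading skill


DDM_BLOCK = ("v_comp", "d_comp", "a")
REDUCED_TERMS = ("ctopp_pa", "ctopp_ran", "nonverbal_iq")


def additive_model_selection(data: pd.DataFrame, outcome: str = "reading") -> dict:
    """Additive risk-factor model of reading skill with nested F-test.

    All-subsets AIC selection over v_comp, d_comp, a, PA, RAN, nonverbal IQ,
    ADHD and age. The DDM block's incremental contribution is tested by an
    F-test of PA+RAN+IQ against PA+RAN+IQ+{v_comp,d_comp,a}; AIC/BIC of the
    selected and reduced models are reported.
    """
    predictors = [*DDM_BLOCK, *REDUCED_TERMS, "adhd", "age"]
    df = data.dropna(subset=[outcome, *predictors]).copy()
    y = zscore(df[outcome])
    X = pd.DataFrame(index=df.index)
    for col in predictors:
        vals = df[col].astype(float)
        X[col] = vals if set(np.unique(vals)) <= {0.0, 1.0} else zscore(vals)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    selected_terms, selected = _all_subsets_ols(y, X, predictors)
    reduced = sm.OLS(y, sm.add_constant(X[list(REDUCED_TERMS)])).fit()
    full = sm.OLS(y, sm.add_constant(X[[*REDUCED_TERMS, *DDM_BLOCK]])).fit()
    f_stat, f_p, f_df = full.compare_f_test(reduced)
    return {
        "selected": _ols_table(selected, "reading ~ AIC-selected additive model"),
        "selected_terms": list(selected_terms),
        "ddm_block_retained": any(t in selected_terms for t in DDM_BLOCK),
        "f_test": {"F": float(f_stat), "p": float(f_p), "df_num": float(f_df),
                   "df_resid_full": float(full.df_resid),
                   "df_resid_reduced": float(reduced.df_resid)},
        "reduced": _ols_table(reduced, "reading ~ PA + RAN + IQ"),
        "full": _ols_table(full, "reading ~ PA + RAN + IQ + DDM block"),
    }


# ---------------------------------------------------------------------------
# lasso


def lasso_cv(X: pd.DataFrame, y, seed: int = 0, n_folds: int = 10,
             n_alphas: int = 100) -> dict:
    """L1-penalized regression with 10-fold CV; penalty at CV minimum."""
    if len(X) < n_folds:
        raise ValueError(f"n={len(X)} smaller than {n_folds} folds")
    Xz = np.column_stack([zscore(X[c]) for c in X.columns])
    yz = zscore(y)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=n_alphas, cv=cv, random_state=seed).fit(Xz, yz)
    coefs = pd.Series(model.coef_, index=list(X.columns), name="coef")
    return {
        "coefficients": coefs,
        "alpha": float(model.alpha_),
        "alphas": model.alphas_,
        "cv_mse_path": model.mse_path_.mean(axis=1),
        "support": list(coefs.index[np.abs(coefs) > 1e-10]),
    }


# ---------------------------------------------------------------------------
# mediation


def mediation_analysis(
    data: pd.DataFrame,
    x: str,
    mediator: str,
    outcome: str,
    covariates: tuple = (),
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Product-of-coefficients mediation with percentile bootstrap CIs.

    a-path: mediator ~ x (+ covariates); b-path and direct effect:
    outcome ~ x + mediator (+ covariates); indirect = a*b; total = direct +
    indirect for these linear models. Reports the proportion mediated
    (indirect / total).
    """
    df = data.dropna(subset=[x, mediator, outcome, *covariates]).copy()
    if len(df) < 50:
        raise ValueError(f"need >= 50 complete cases, got {len(df)}")
    if df[mediator].std(ddof=0) < 1e-12:
        raise ValueError("zero-variance mediator")
    cols = [x, mediator, outcome, *covariates]
    Z = pd.DataFrame({c: zscore(df[c]) for c in cols})

    def _effects(frame: pd.DataFrame) -> tuple[float, float, float]:
        Xa = sm.add_constant(frame[[x, *covariates]])
        a_path = sm.OLS(frame[mediator], Xa).fit().params[x]
        Xb = sm.add_constant(frame[[x, mediator, *covariates]])
        fit_b = sm.OLS(frame[outcome], Xb).fit()
        return float(a_path * fit_b.params[mediator]), float(fit_b.params[x]), \
            float(a_path)

    indirect, direct, _ = _effects(Z)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    idx = np.arange(len(Z))
    for b in range(n_boot):
        sample = Z.iloc[rng.choice(idx, size=len(idx), replace=True)]
        boots[b] = _effects(sample)[:2]
    lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
    ind_ci = tuple(np.percentile(boots[:, 0], [lo, hi]))
    dir_ci = tuple(np.percentile(boots[:, 1], [lo, hi]))
    total = indirect + direct
    return {
        "indirect": indirect, "indirect_ci": ind_ci,
        "direct": direct, "direct_ci": dir_ci,
        "total": total,
        "proportion_mediated": indirect / total if abs(total) > 1e-12 else np.nan,
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# subgroup analysis


def mean_drift(fits: pd.DataFrame) -> np.ndarray:
    """Mean of per-coherence z-scored drift estimates (z over the full cohort)."""
    return np.column_stack([zscore(fits[c]) for c in ("v6", "v12", "v24", "v48")]).mean(axis=1)


def subgroup_analysis(
    data: pd.DataFrame,
    score: str,
    cutoff: float,
    outcome: str = "reading",
    min_n: int = 10,
) -> dict:
    """Reading-drift correlation within a high-scoring stratum.

    ``data`` must carry a ``mean_drift`` column computed on the full cohort
    (z-scoring precedes subsetting). Reports the subgroup Pearson r and the
    partial model controlling RAN and nonverbal IQ.
    """
    sub = data[data[score] >= cutoff]
    if len(sub) < min_n:
        raise ValueError(f"subgroup too small: n={len(sub)} below {min_n}")
    r, p = stats.pearsonr(sub[outcome], sub["mean_drift"])
    X = pd.DataFrame({
        "mean_drift": zscore(sub["mean_drift"]),
        "ctopp_ran": zscore(sub["ctopp_ran"]),
        "nonverbal_iq": zscore(sub["nonverbal_iq"]),
    }, index=sub.index)
    res = sm.OLS(zscore(sub[outcome]), sm.add_constant(X)).fit()
    return {
        "n": int(len(sub)),
        "r": float(r),
        "p": float(p),
        "partial_model": _ols_table(res, f"{outcome} ~ mean_drift + RAN + IQ | {score} >= {cutoff}"),
    }
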