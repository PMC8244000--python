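"""Exploratory factor analysis of DDM parameters, phonological subtests, and IQ.

Factor retention combines the Kaiser rule (correlation-matrix eigenvalues
greater than 1) with Horn's parallel analysis (observed eigenvalues against
the 95th percentile of eigenvalues from random normal data of the same
shape). Extraction is by maximum likelihood with orthogonal varimax
rotation; factor scores use the regression (Thurstone) method. Held-out
predictive comparison of the k-factor and best-single-factor models of
reading skill uses leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.multivariate.factor import Factor

#: Uniquenesses below this are Heywood cases; they are floored and flagged.
UNIQUENESS_FLOOR = 0.005


@dataclass
class FactorModel:
    loadings: pd.DataFrame  # variables x factors, varimax-rotated
    eigenvalues: np.ndarray  # of the observed correlation matrix
    uniquenesses: pd.Series
    communalities: pd.Series
    explained_variance: pd.Series  # per-factor SS loadings / n variables
    explained_variance_total: float
    scores: pd.DataFrame  # subjects x factors, regression method
    rotation: str
    heywood: bool


def _correlation_eigenvalues(X: np.ndarray) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def retain_factors(
    data: pd.DataFrame | np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
) -> dict:
    """Factor-retention counts by the Kaiser rule and parallel analysis.

    Parallel analysis counts leading observed eigenvalues exceeding the
    ``percentile`` of the eigenvalue distribution from ``n_sim`` standard
    normal datasets of the same shape, stopping at the first failure.
    The returned ``k`` is the parallel-analysis count.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if np.any(X.std(axis=0, ddof=0) < 1e-12):
        raise ValueError("constant column in data matrix")
    obs = _correlation_eigenvalues(X)
    kaiser = int((obs > 1.0).sum())

    rng = np.random.default_rng(seed)
    sim = np.empty((n_sim, p))
    for s in range(n_sim):
        sim[s] = _correlation_eigenvalues(rng.standard_normal((n, p)))
    thresholds = np.percentile(sim, percentile, axis=0)
    k = 0
    for lam, thr in zip(obs, thresholds):
        if lam > thr:
            k += 1
        else:
            break
    return {"k": k, "parallel": k, "kaiser": kaiser,
            "eigenvalues": obs, "thresholds": thresholds}


def efa_varimax(data: pd.DataFrame, k: int) -> FactorModel:
    """Maximum-likelihood EFA with varimax rotation and regression scores.

    Explained variance is reported per factor as the rotated sum of squared
    loadings over the number of variables (shares sum to the total
    communality fraction). Heywood cases (uniqueness below the floor) are
    floored and flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = list(data.columns)
    X = data.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    eigs = _correlation_eigenvalues(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(Z, n_factor=k, method="ml")
        res = fa.fit()
    loadings = np.asarray(res.loadings)[:, :k]
    if k > 1:
        res.rotate("varimax")
        loadings = np.asarray(res.loadings)[:, :k]

    uniq = 1.0 - (loadings**2).sum(axis=1)
    heywood = bool((uniq < UNIQUENESS_FLOOR).any())
    uniq = np.maximum(uniq, UNIQUENESS_FLOOR)
    comm = 1.0 - uniq

    # orient each factor so its largest-magnitude loading is positive
    for j in range(k):
        jmax = np.argmax(np.abs(loadings[:, j]))
        if loadings[jmax, j] < 0:
            loadings[:, j] *= -1
    factor_names = [f"factor{j + 1}" for j in range(k)]
    L = pd.DataFrame(loadings, index=cols, columns=factor_names)

    ss = (loadings**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    L = L.iloc[:, order]
    L.columns = factor_names
    ss = ss[order]

    # regression (Thurstone) factor scores: Z R^-1 Lambda
    R = np.corrcoef(X, rowvar=False)
    B = np.linalg.solve(R, L.to_numpy())
    scores = pd.DataFrame(Z @ B, columns=factor_names, index=data.index)

    explained = pd.Series(ss / len(cols), index=factor_names)
    return FactorModel(
        loadings=L,
        eigenvalues=eigs,
        uniquenesses=pd.Series(uniq, index=cols),
        communalities=pd.Series(comm, index=cols),
        explained_variance=explained,
        explained_variance_total=float(explained.sum()),
        scores=scores,
        rotation="varimax" if k > 1 else "none",
        heywood=heywood,
    )


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tucker congruence matrix between columns of two loading matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.sqrt(np.outer((A**2).sum(axis=0), (B**2).sum(axis=0)))
    return num / den


def match_factors(recovered: np.ndarray, planted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match recovered factor columns to planted ones by |congruence|.

    Returns (column permutation of recovered, per-factor congruence after
    sign alignment).
    """
    from scipy.optimize import linear_sum_assignment

    C = tucker_congruence(recovered, planted)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(planted.shape[1], dtype=int)
    congr = np.empty(planted.shape[1])
    for r, c in zip(rows, cols):
        perm[c] = r
        congr[c] = abs(C[r, c])
    return perm, congr


def factor_loocv_prediction(
    scores: pd.DataFrame,
    outcome,
    single_factor: str | None = None,
) -> dict:
    """Held-out R^2 of the k-factor vs the best single-factor model.

    For each left-out subject the regression of reading skill on factor
    scores is refit on the remainder; held-out R^2 = 1 - SSE/SST. The single
    factor defaults to the one with the highest full-data R^2.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 subjects for LOO-CV")
    if scores.isna().any().any() or np.isnan(y).any():
        raise ValueError("scores and outcome must be complete")
    S = scores.reset_index(drop=True)

    if single_factor is None:
        r2 = {
            c: sm.OLS(y, sm.add_constant(S[[c]])).fit().rsquared for c in S.columns
        }
        single_factor = max(r2, key=r2.get)

    def _loo_r2(cols: list[str]) -> float:
        X = sm.add_constant(S[cols]).to_numpy()
        preds = np.empty(len(y))
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            preds[i] = X[i] @ beta
        sse = float(((y - preds) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        return 1.0 - sse / sst

    full_fit = sm.OLS(y, sm.add_constant(S)).fit()
    single_fit = sm.OLS(y, sm.add_constant(S[[single_factor]])).fit()
    return {
        "r2_loo_full": _loo_r2(list(S.columns)),
        "r2_loo_single": _loo_r2([single_factor]),
        "single_factor": single_factor,
        "aic_full": float(full_fit.aic), "bic_full": float(full_fit.bic),
        "aic_single": float(single_fit.aic), "bic_single": float(single_fit.bic),
    }
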