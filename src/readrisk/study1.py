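"""Classification of diagnosis from PA and RAN, effect sizes, age-interaction models.

Quadratic discriminant analysis gives each diagnosis group its own Gaussian
(mean and covariance); posterior classification uses Bayes' rule with
empirical class priors. Accuracy, sensitivity and specificity come from
leave-one-out cross-validation so the reported rates are out-of-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_predict


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_ci_halfwidth: float
    confusion: dict
    predictions: np.ndarray
    n: int


@dataclass
class CoefficientTable:
    """Fitted-model summary: term estimates, SEs, p-values, AIC/BIC."""

    table: pd.DataFrame
    aic: float
    bic: float
    partial_r2: dict = field(default_factory=dict)
    model_name: str = ""


def qda_loo(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    positive_label=True,
) -> ClassificationReport:
    """QDA with leave-one-out cross-validation.

    ``positive_label`` marks the diagnosis class for sensitivity. Class
    priors are empirical. Near-singular class covariances are ridged with a
    small regularization proportional to the mean feature variance.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be 2-dimensional")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("need >= 2 observations per class")

    def _fit_predict(reg: float) -> np.ndarray:
        clf = QuadraticDiscriminantAnalysis(reg_param=reg)
        with np.errstate(over="ignore", invalid="raise", divide="raise"):
            return cross_val_predict(clf, X, y, cv=LeaveOneOut())

    try:
        pred = _fit_predict(0.0)
    except (FloatingPointError, np.linalg.LinAlgError):
        try:
            pred = _fit_predict(1e-6)
        except (FloatingPointError, np.linalg.LinAlgError) as err:
            raise np.linalg.LinAlgError(
                "class covariance singular even after regularization") from err

    pos = y == positive_label
    pred_pos = pred == positive_label
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    n = len(y)
    acc = (tp + tn) / n
    return ClassificationReport(
        accuracy=acc,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy_ci_halfwidth=float(1.96 * np.sqrt(acc * (1 - acc) / n)),
        confusion={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        predictions=pred,
        n=n,
    )


def cohens_d_disattenuated(
    group_a: np.ndarray,
    group_b: np.ndarray,
    reliability: float,
) -> tuple[float, float]:
    """Pooled-SD Cohen's d and its dis-attenuated version d / sqrt(reliability).

    Dis-attenuation corrects the standardized mean difference for test-retest
    unreliability of the measure.
    """
    if not 0 < reliability <= 1:
        raise ValueError(f"reliability must be in (0, 1], got {reliability}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    d_raw = float((a.mean() - b.mean()) / pooled)
    return d_raw, d_raw / float(np.sqrt(reliability))


def _check_collinearity(df: pd.DataFrame, cols: list[str]) -> None:
    X = df[cols].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X, tol=1e-8 * np.abs(X).max()) < X.shape[1]:
        raise ValueError(f"perfect collinearity among predictors {cols}")


def _coef_table(res, name: str) -> CoefficientTable:
    tab = pd.DataFrame({
        "term": res.params.index,
        "beta": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "p": res.pvalues.to_numpy(),
    }).reset_index(drop=True)
    return CoefficientTable(table=tab, aic=float(res.aic), bic=float(res.bic), model_name=name)


def fit_interaction_models(scores: pd.DataFrame) -> dict[str, CoefficientTable]:
    """Age-interaction models of diagnosis and pseudoword reading.

    Fits (1) logistic diagnosis ~ age + PA + age:PA, and linear models of
    pseudoword reading on (2) age * PA and (3) age * RAN, with Wald
    inference. Expects columns diagnosis, age, pa, ran, pseudoword.
    """
    df = scores.copy()
    df["diagnosis"] = df["diagnosis"].astype(int)
    _check_collinearity(df, ["age", "pa", "ran"])

    out: dict[str, CoefficientTable] = {}
    logit = smf.logit("diagnosis ~ age + pa + age:pa", data=df).fit(disp=0)
    if not np.isfinite(logit.bse).all():
        raise ValueError("logistic model shows separation or collinearity (non-finite SEs)")
    out["diagnosis_age_pa"] = _coef_table(logit, "logit diagnosis ~ age*PA")
    for label, formula in (
        ("pseudoword_age_pa", "pseudoword ~ age * pa"),
        ("pseudoword_age_ran", "pseudoword ~ age * ran"),
    ):
        res = smf.ols(formula, data=df).fit()
        out[label] = _coef_table(res, formula)
    return out
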