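"""Drift diffusion model: generative model, likelihood, and per-subject fitting.

The model describes two-alternative forced-choice behaviour on the random-dot
motion task: noisy evidence accumulates from a starting point ``z = z_rel * a``
toward absorbing boundaries at 0 (error) and ``a`` (correct) with drift ``v_c``
that depends on stimulus coherence. Reaction time is the first-passage time
plus a non-decision component. Across-trial variability enters through a
Gaussian drift distribution (sd ``s_v``), a uniform starting point (range
``s_z``) and a uniform non-decision time (range ``s_t``).

All quantities use the sigma = 1 diffusion-coefficient convention; estimates
under Ratcliff's sigma = 0.1 convention are obtained by multiplying v, a, s_v
and s_z by 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from . import _kernels

#: Coherence levels (percent) entering the DDM analysis, in drift-slot order.
ANALYSIS_COHERENCES = (6, 12, 24, 48)
#: The full task design includes a 100% coherence condition excluded from fits.
DESIGN_COHERENCES = (6, 12, 24, 48, 100)

#: Gauss-Legendre quadrature order for the uniform s_z / s_t mixtures.
QUAD_ORDER = 11
_GL_X, _GL_W = np.polynomial.legendre.leggauss(QUAD_ORDER)

#: Per-trial density floor, bounding the influence of any single outlier.
DENSITY_FLOOR = 1e-10

#: Euler step (s) and decision-time cap (s) for simulation; the cap mirrors
#: the 10 s response deadline of the task.
EULER_DT = 5e-4
DECISION_CAP = 10.0


@dataclass
class DDMParameters:
    """Nine-parameter generative model for one subject.

    v6..v48 are drift rates (evidence/s) per coherence condition, ``a`` the
    boundary separation, ``t_nd`` mean non-decision time (s), ``s_t`` and
    ``s_z`` the full ranges of the uniform non-decision-time and
    starting-point variability, ``s_v`` the sd of across-trial drift
    variability. ``z_rel`` is the mean relative starting point, fixed at 0.5
    for the symmetric left/right task.
    """

    v6: float
    v12: float
    v24: float
    v48: float
    a: float
    t_nd: float
    s_t: float = 0.0
    s_z: float = 0.0
    s_v: float = 0.0
    z_rel: float = 0.5

    def validate(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not 0 < self.z_rel < 1:
            raise ValueError(f"relative start must lie in (0,1), got z_rel={self.z_rel}")
        if self.t_nd - self.s_t / 2 < 0:
            raise ValueError(
                f"non-decision time support extends below zero (t_nd={self.t_nd}, s_t={self.s_t})"
            )
        if self.s_t < 0 or self.s_v < 0 or self.s_z < 0:
            raise ValueError("variability parameters must be non-negative")
        z_max = 2 * self.a * min(self.z_rel, 1 - self.z_rel)
        if self.s_z >= z_max > 0:
            raise ValueError(f"s_z={self.s_z} places starting points outside (0, a)")

    def drift(self, coherence: int) -> float:
        try:
            return {6: self.v6, 12: self.v12, 24: self.v24, 48: self.v48}[int(coherence)]
        except KeyError:
            raise KeyError(f"no drift rate for coherence {coherence}%") from None

    @property
    def drifts(self) -> np.ndarray:
        return np.array([self.v6, self.v12, self.v24, self.v48])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitConfig:
    """Multi-start bounded maximum-likelihood settings for :func:`fit_subject`."""

    n_starts: int = 10
    n_polish: int = 3
    maxfev: int = 1500
    xatol: float = 1e-3
    fatol: float = 1e-3
    min_trials_per_coherence: int = 40
    refine_maxiter: int = 40
    #: sd of the half-normal shrinkage on s_v (None disables). Weak
    #: regularization of the well-known drift/drift-variability likelihood
    #: ridge, which otherwise produces runaway joint (v, s_v) estimates in a
    #: minority of 240-trial datasets and contaminates drift recovery.
    s_v_shrinkage_sd: float | None = 0.8
    # bounds: (v x4, a, t_nd, s_t/(2*t_nd) fraction, s_z/a fraction, s_v);
    # the fractional slots keep t_nd - s_t/2 >= 0 and s_z <= 0.9*a as a box
    lower: tuple = (0.0, 0.0, 0.0, 0.0, 0.3, 0.1, 0.0, 0.0, 0.0)
    upper: tuple = (8.0, 8.0, 8.0, 8.0, 4.0, 1.5, 0.9, 0.9, 3.0)


@dataclass
class FitResult:
    params: DDMParameters
    nll: float
    converged: bool
    n_trials_used: int
    starts_tried: int
    diagnostics: dict = field(default_factory=dict)


def choice_probability(v: float, a: float, z_rel: float = 0.5) -> float:
    """Probability of absorption at the correct (upper) boundary, no variability.

    Closed form (1 - exp(-2 v a z_rel)) / (1 - exp(-2 v a)) with sigma = 1;
    the v -> 0 limit is z_rel.
    """
    if not a > 0:
        raise ValueError(f"boundary separation must be positive, got a={a}")
    if not 0 < z_rel < 1:
        raise ValueError(f"relative start must lie in (0,1), got z_rel={z_rel}")
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return float(z_rel)
    # guard exp overflow at extreme drift
    if x > 500:
        return float(-np.expm1(-x * z_rel))
    if x < -500:
        return float(np.exp(x * (1 - z_rel)))
    return float(np.expm1(-x * z_rel) / np.expm1(-x))


def fpt_density(v: float, a: float, z_rel: float, t, boundary: str = "correct"):
    """First-passage density of the simple DDM (no variability, no t_nd).

    Vectorized over ``t``; integrates over t (per boundary) to the
    corresponding absorption probability.
    """
    if not a > 0 or not 0 < z_rel < 1:
        raise ValueError("invalid a or z_rel")
    upper = _boundary_flag(boundary)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr.ravel()):
        out.ravel()[i] = _kernels.simple_density(ti, v, a, z_rel, upper)
    return out if np.ndim(t) else float(out[0])


def full_fpt_density(params: DDMParameters, coherence: int, t, boundary: str = "correct"):
    """Density of (boundary, rt) under the full model, vectorized over t."""
    params.validate()
    upper = _boundary_flag(boundary)
    v = params.drift(coherence)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr.ravel()):
        out.ravel()[i] = _kernels.full_density(
            ti, upper, v, params.a, params.z_rel, params.t_nd,
            params.s_t, params.s_z, params.s_v, _GL_X, _GL_W,
        )
    return out if np.ndim(t) else float(out[0])


def _boundary_flag(boundary: str) -> bool:
    if boundary not in ("correct", "error"):
        raise ValueError(f"boundary must be 'correct' or 'error', got {boundary!r}")
    return boundary == "correct"


def simulate_trials(
    params: DDMParameters,
    design: Mapping[int, int],
    seed: int,
    dt: float = EULER_DT,
    cap: float = DECISION_CAP,
    extra_drifts: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Simulate a trial table from the full generative model.

    ``design`` maps coherence (percent, from the task design set) to trial
    count. Coherences without a fitted drift slot (i.e. 100%) require an
    entry in ``extra_drifts``. Reproducible given ``seed``.
    """
    params.validate()
    rows = []
    ss = np.random.SeedSequence(seed)
    for coherence in sorted(design):
        n = int(design[coherence])
        if n < 0:
            raise ValueError("design counts must be >= 0")
        if coherence not in DESIGN_COHERENCES:
            raise ValueError(f"coherence {coherence}% is not in the task design set")
        if n == 0:
            continue
        if extra_drifts and coherence in extra_drifts:
            v = float(extra_drifts[coherence])
        else:
            v = params.drift(coherence)
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        rt, correct, capped = _kernels.simulate(
            n, v, params.a, params.z_rel, params.t_nd,
            params.s_t, params.s_z, params.s_v, dt, cap, sub_seed,
        )
        rows.append(pd.DataFrame({
            "coherence": coherence, "correct": correct, "rt": rt, "capped": capped,
        }))
    if not rows:
        return pd.DataFrame(columns=["coherence", "correct", "rt", "capped"])
    return pd.concat(rows, ignore_index=True)


def _trial_arrays(trials: pd.DataFrame):
    coh = trials["coherence"].to_numpy()
    slot = np.searchsorted(np.array(ANALYSIS_COHERENCES), coh)
    bad = (slot >= len(ANALYSIS_COHERENCES)) | (np.array(ANALYSIS_COHERENCES)[
        np.clip(slot, 0, 3)] != coh)
    if bad.any():
        raise ValueError(
            f"trials contain coherences outside the analysis set: {sorted(set(coh[bad]))}"
        )
    return (
        trials["rt"].to_numpy(dtype=float),
        trials["correct"].to_numpy(dtype=bool),
        slot.astype(np.int64),
    )


def negative_log_likelihood(params: DDMParameters, trials: pd.DataFrame) -> float:
    """Sum of -log full density over trials, floored at DENSITY_FLOOR per trial."""
    params.validate()
    if len(trials) == 0:
        warnings.warn("empty trial list; NLL defined as 0", stacklevel=2)
        return 0.0
    rt, correct, slot = _trial_arrays(trials)
    theta = np.array([
        params.v6, params.v12, params.v24, params.v48,
        params.a, params.t_nd, params.s_t, params.s_z, params.s_v,
    ])
    return float(_kernels.nll(theta, rt, correct, slot, params.z_rel, _GL_X, _GL_W, DENSITY_FLOOR))


def _theta_to_params(theta: np.ndarray) -> DDMParameters:
    # internal vector stores s_t as a fraction of 2*t_nd (capped at the
    # absolute bound) and s_z as a fraction of a, so the parameter-validity
    # constraints are a fixed box and the objective is smooth inside it
    a, t_nd = theta[4], theta[5]
    s_t = min(theta[6] * 2.0 * t_nd, _S_T_CAP)
    return DDMParameters(
        v6=theta[0], v12=theta[1], v24=theta[2], v48=theta[3],
        a=a, t_nd=t_nd, s_t=s_t, s_z=theta[7] * a, s_v=theta[8],
    )


_S_T_CAP = 0.8


def _objective(theta, rt, correct, slot, floor, shrink_sd=None):
    a, t_nd = theta[4], theta[5]
    kern_theta = np.asarray(theta, dtype=float).copy()
    kern_theta[6] = min(theta[6] * 2.0 * t_nd, _S_T_CAP)
    kern_theta[7] = theta[7] * a
    out = _kernels.nll(kern_theta, rt, correct, slot, 0.5, _GL_X, _GL_W, floor)
    if shrink_sd is not None:
        out += 0.5 * (theta[8] / shrink_sd) ** 2
    return out


def _heuristic_start(trials: pd.DataFrame, config: FitConfig) -> np.ndarray:
    a0 = 1.4
    t0 = float(np.clip(0.9 * trials["rt"].min(), config.lower[5] + 0.01, 1.0))
    theta = np.empty(9)
    for k, coh in enumerate(ANALYSIS_COHERENCES):
        sub = trials[trials["coherence"] == coh]
        p = float(np.clip(sub["correct"].mean(), 0.52, 0.995)) if len(sub) else 0.7
        theta[k] = np.clip(np.log(p / (1 - p)) / a0, 0.05, 7.5)
    theta[4] = a0
    theta[5] = t0
    theta[6] = 0.2
    theta[7] = 0.2
    theta[8] = 0.5
    return theta


def fit_subject(trials: pd.DataFrame, config: FitConfig | None = None, seed: int = 0) -> FitResult:
    """Fit the 9-parameter model to one subject by multi-start bounded MLE.

    Only valid trials at the 6-48% analysis coherences are used. Sobol
    quasi-random starts plus a moment-based heuristic start are screened by
    raw NLL; Nelder-Mead polish runs from the best ``n_polish``.
    """
    config = config or FitConfig()
    use = trials[trials["coherence"].isin(ANALYSIS_COHERENCES)]
    if "valid" in use.columns:
        use = use[use["valid"]]
    counts = use.groupby("coherence").size()
    for coh in ANALYSIS_COHERENCES:
        if counts.get(coh, 0) < config.min_trials_per_coherence:
            raise ValueError(
                f"insufficient valid trials at {coh}% coherence "
                f"({counts.get(coh, 0)} < {config.min_trials_per_coherence})"
            )
    rt, correct, slot = _trial_arrays(use)

    if float(np.std(rt)) < 1e-9:
        # degenerate RT distribution: nothing identifiable, flag and return
        return FitResult(
            params=_theta_to_params(np.array(config.lower, dtype=float) + 0.1),
            nll=np.nan, converged=False, n_trials_used=len(use),
            starts_tried=0, diagnostics={"degenerate_rts": True},
        )

    lower = np.array(config.lower, dtype=float)
    upper = np.array(config.upper, dtype=float)
    sampler = qmc.Sobol(d=9, seed=seed)
    n_qr = max(config.n_starts - 1, 0)
    n_draw = 1 << max(int(np.ceil(np.log2(max(n_qr, 1)))), 0)
    starts = [lower + (upper - lower) * row for row in sampler.random(n_draw)[:n_qr]]
    starts.append(_heuristic_start(use, config))

    args = (rt, correct, slot, DENSITY_FLOOR, config.s_v_shrinkage_sd)
    bounds = list(zip(lower, upper))
    screened = sorted(starts, key=lambda th: _objective(np.asarray(th), *args))
    best = None
    best_idx = -1
    for idx, start in enumerate(screened[: config.n_polish]):
        res = minimize(
            _objective, np.asarray(start), args=args, method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxfev": config.maxfev, "xatol": config.xatol,
                "fatol": config.fatol, "adaptive": True,
            },
        )
        if best is None or res.fun < best.fun - 1e-12:
            best, best_idx = res, idx
    # gradient-based refinement from the best simplex solution; the
    # likelihood is smooth inside the (transformed) box
    refined = minimize(
        _objective, best.x, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": config.refine_maxiter},
    )
    if refined.fun <= best.fun:
        theta = np.asarray(refined.x)
        objective_value = float(refined.fun)
        converged = bool(refined.success or best.success)
    else:
        theta = np.asarray(best.x)
        objective_value = float(best.fun)
        converged = bool(best.success)
    # report the unpenalized data NLL at the optimum
    final_nll = float(_objective(theta, rt, correct, slot, DENSITY_FLOOR))
    at_bound = {}
    names = ["v6", "v12", "v24", "v48", "a", "t_nd", "s_t_frac", "s_z_frac", "s_v"]
    span = upper - lower
    for i, name in enumerate(names):
        at_bound[name] = bool(
            theta[i] - lower[i] < 1e-4 * span[i] and lower[i] > 0
        ) or bool(upper[i] - theta[i] < 1e-4 * span[i])
    return FitResult(
        params=_theta_to_params(theta),
        nll=final_nll,
        converged=converged,
        n_trials_used=len(use),
        starts_tried=len(starts),
        diagnostics={"at_bound": at_bound, "best_start_index": best_idx,
                     "objective_value": objective_value},
    )
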