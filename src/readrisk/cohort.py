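"""Synthetic cohort generation for both studies.

The generators plant the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable and testable without any
external download:

* :func:`generate_study1_cohort` draws two diagnosis groups from a bivariate
  Gaussian on the standard-score scale, separated by configurable effect
  sizes on phonological awareness (default d = 0.93) and rapid naming
  (default d = 0.81).
* :func:`generate_study2_cohort` draws four orthogonal latent factors
  (visual encoding, phonology + nonverbal IQ, rapid naming, decision
  variability), maps them through a loading matrix to observed DDM
  parameters and behavioral scores, builds reading skill as a weighted
  factor sum (or, in the cascade variant, purely from observed PA), and
  simulates each subject's trial-level session from their true DDM
  parameters. Truth tables are retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import ANALYSIS_COHERENCES, DDMParameters, simulate_trials

# ---------------------------------------------------------------------------
# Study 1


@dataclass
class Study1Config:
    """Two-group bivariate score generator on the standard-score scale."""

    n_dyslexic: int = 110
    n_control: int = 105
    d_pa: float = 0.93
    d_ran: float = 0.81
    r_pa_ran: float = 0.45
    control_mean: float = 100.0
    sd: float = 15.0
    age_range: tuple[float, float] = (5.0, 17.0)
    # pseudoword-reading generator: standardized weights + optional planted
    # age interactions (in per-year units on z-scored predictors)
    b_pa: float = 0.35
    b_ran: float = 0.35
    b_age: float = 0.0
    b_age_pa: float = 0.0
    b_age_ran: float = 0.0
    pseudoword_noise_sd: float = 0.8

    def validate(self) -> None:
        if self.n_dyslexic <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        if self.sd <= 0:
            raise ValueError("score SD must be positive")
        if not abs(self.r_pa_ran) < 1:
            raise ValueError("|r(PA,RAN)| must be < 1")


def generate_study1_cohort(config: Study1Config, seed: int) -> pd.DataFrame:
    """Labeled PA/RAN/pseudoword score table with a diagnosis flag."""
    config.validate()
    rng = np.random.default_rng(seed)
    cov = config.sd**2 * np.array([[1.0, config.r_pa_ran], [config.r_pa_ran, 1.0]])
    rows = []
    for group, n, shift in (
        ("Control", config.n_control, 0.0),
        ("Dyslexic", config.n_dyslexic, 1.0),
    ):
        mean = np.array([
            config.control_mean - shift * config.d_pa * config.sd,
            config.control_mean - shift * config.d_ran * config.sd,
        ])
        scores = rng.multivariate_normal(mean, cov, size=n)
        rows.append(pd.DataFrame({
            "group": group,
            "diagnosis": group == "Dyslexic",
            "pa": scores[:, 0],
            "ran": scores[:, 1],
        }))
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "subject_id", [f"s1_{i:04d}" for i in range(len(out))])
    out["age"] = rng.uniform(*config.age_range, size=len(out))

    z_pa = (out["pa"] - config.control_mean) / config.sd
    z_ran = (out["ran"] - config.control_mean) / config.sd
    z_age = (out["age"] - out["age"].mean()) / out["age"].std()
    pseudo_z = (
        config.b_pa * z_pa + config.b_ran * z_ran + config.b_age * z_age
        + config.b_age_pa * z_age * z_pa + config.b_age_ran * z_age * z_ran
        + config.pseudoword_noise_sd * rng.standard_normal(len(out))
    )
    out["pseudoword"] = config.control_mean + config.sd * pseudo_z
    return out


# ---------------------------------------------------------------------------
# Study 2

#: Observed variables entering the factor model, in canonical order.
OBSERVED_VARS = (
    "v6", "v12", "v24", "v48", "s_v",
    "elision", "blending", "sound_matching", "nonword_rep", "nonverbal_iq",
    "rapid_digits", "rapid_letters",
    "s_t", "t_nd", "s_z",
    "a",
)

FACTOR_NAMES = ("visual_encoding", "phonology_iq", "rapid_naming", "decision_variability")


def default_loadings() -> pd.DataFrame:
    """Default 4-factor loading matrix (variables x factors).

    Factor 1 loads the drift rates and s_v; factor 2 the PA subtests,
    phonological memory, and nonverbal IQ; factor 3 the rapid-naming
    subtests; factor 4 the non-decision-time and variability parameters.
    The boundary separation ``a`` loads on no factor (pure uniqueness).
    """
    L = pd.DataFrame(0.0, index=list(OBSERVED_VARS), columns=list(FACTOR_NAMES))
    L.loc["v6", "visual_encoding"] = 0.75
    L.loc["v12", "visual_encoding"] = 0.85
    L.loc["v24", "visual_encoding"] = 0.85
    L.loc["v48", "visual_encoding"] = 0.80
    L.loc["s_v", "visual_encoding"] = 0.50
    L.loc["elision", "phonology_iq"] = 0.80
    L.loc["blending", "phonology_iq"] = 0.78
    L.loc["sound_matching", "phonology_iq"] = 0.75
    L.loc["nonword_rep", "phonology_iq"] = 0.60
    L.loc["nonverbal_iq", "phonology_iq"] = 0.50
    L.loc["rapid_digits", "rapid_naming"] = 0.85
    L.loc["rapid_letters", "rapid_naming"] = 0.85
    L.loc["s_t", "decision_variability"] = 0.80
    L.loc["t_nd", "decision_variability"] = 0.75
    L.loc["s_z", "decision_variability"] = 0.60
    return L


def cascade_loadings() -> pd.DataFrame:
    """Loading matrix for the cascading-deficit variant.

    A single sensory factor drives both the DDM parameters and the
    phonological subtests, so any DDM-reading association must travel
    through phonology.
    """
    L = pd.DataFrame(0.0, index=list(OBSERVED_VARS), columns=list(FACTOR_NAMES))
    for var, lam in (("v6", 0.6), ("v12", 0.7), ("v24", 0.7), ("v48", 0.65), ("s_v", 0.4),
                     ("elision", 0.75), ("blending", 0.72), ("sound_matching", 0.7),
                     ("nonword_rep", 0.55),
                     ("s_t", 0.5), ("t_nd", 0.45), ("s_z", 0.4)):
        L.loc[var, "visual_encoding"] = lam
    L.loc["rapid_digits", "rapid_naming"] = 0.85
    L.loc["rapid_letters", "rapid_naming"] = 0.85
    L.loc["nonverbal_iq", "phonology_iq"] = 0.7
    return L


#: Natural location/scale for each observed variable (affine map applied to
#: the standardized generated value). Behavioral scores use the standard
#: score scale (mean 100, SD 15); DDM parameters use task-plausible units.
NATURAL_SCALES: dict[str, tuple[float, float]] = {
    "v6": (1.0, 0.40),
    "v12": (1.5, 0.50),
    "v24": (2.2, 0.60),
    "v48": (3.0, 0.75),
    "s_v": (0.6, 0.20),
    "a": (1.3, 0.25),
    "t_nd": (0.45, 0.07),
    "s_t": (0.20, 0.06),
    "s_z": (0.35, 0.12),
    "elision": (100.0, 15.0),
    "blending": (100.0, 15.0),
    "sound_matching": (100.0, 15.0),
    "nonword_rep": (100.0, 15.0),
    "nonverbal_iq": (100.0, 15.0),
    "rapid_digits": (100.0, 15.0),
    "rapid_letters": (100.0, 15.0),
}


@dataclass
class Study2Config:
    """Latent-factor cohort generator for the psychophysics study."""

    n_subjects: int = 106
    loadings: pd.DataFrame = field(default_factory=default_loadings)
    #: per-variable uniqueness; None derives 1 - communality from loadings
    uniqueness: dict | None = None
    #: weights of reading skill on the four latent factors (z scale).
    #: Decision variability (factor 4) raises s_t/t_nd/s_z, hence hurts
    #: reading; drift (factor 1) helps it.
    reading_weights: tuple = (0.30, 0.50, 0.40, -0.30)
    #: additional direct paths from standardized observed variables to
    #: reading; the default gives the (factor-free) boundary separation its
    #: own additive effect.
    reading_direct_weights: dict = field(default_factory=lambda: {"a": -0.25})
    #: "factors": reading = weighted factor sum (+ direct paths) + noise.
    #: "mediated": reading depends only on the observed PA composite — the
    #: pure cascading-deficit alternative.
    reading_mode: str = "factors"
    mediated_weight: float = 0.7
    #: residual sd of standardized reading; None completes variance to 1
    reading_noise_sd: float | None = None
    trials_per_coherence: int = 60
    include_100: bool = True
    adhd_rate: float = 0.15
    age_mean: float = 9.9
    age_sd: float = 1.3
    age_range: tuple[float, float] = (8.0, 12.0)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        L = self.loadings.to_numpy()
        comm = (L**2).sum(axis=1)
        if (comm > 1.0 + 1e-9).any():
            bad = self.loadings.index[comm > 1.0 + 1e-9].tolist()
            raise ValueError(f"loadings imply communality > 1 for {bad}")
        if self.reading_mode not in ("factors", "mediated"):
            raise ValueError(f"unknown reading_mode {self.reading_mode!r}")


def cascade_config(**overrides) -> Study2Config:
    """Study2Config preset for the pure cascading-deficit generator."""
    cfg = Study2Config(
        loadings=cascade_loadings(),
        reading_mode="mediated",
        reading_direct_weights={},
    )
    return replace(cfg, **overrides)


@dataclass
class Study2Cohort:
    """Generated cohort: observed scores, truth tables, and trial data."""

    scores: pd.DataFrame
    true_params: pd.DataFrame
    factors: pd.DataFrame
    trials: pd.DataFrame | None
    config: Study2Config


def _clip_params(row: pd.Series) -> pd.Series:
    """Project a generated parameter row onto the valid DDM parameter set."""
    row = row.copy()
    for v in ("v6", "v12", "v24", "v48"):
        row[v] = max(row[v], 0.05)
    row["a"] = max(row["a"], 0.4)
    row["s_v"] = max(row["s_v"], 0.01)
    row["t_nd"] = max(row["t_nd"], 0.15)
    row["s_t"] = float(np.clip(row["s_t"], 0.01, 1.9 * row["t_nd"]))
    row["s_z"] = float(np.clip(row["s_z"], 0.01, 0.88 * row["a"]))
    return row


def generate_study2_cohort(
    config: Study2Config,
    seed: int,
    simulate: bool = True,
) -> Study2Cohort:
    """Draw a full synthetic psychophysics cohort.

    Observed variables are Lambda @ factors + unique noise on the z scale,
    then affine-mapped to natural units (and clipped into the valid DDM
    parameter region, with a count of clipped values recorded in
    ``scores.attrs['n_clipped']``).
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_subjects

    L = config.loadings.loc[list(OBSERVED_VARS), list(FACTOR_NAMES)].to_numpy()
    comm = (L**2).sum(axis=1)
    if config.uniqueness is None:
        uniq = 1.0 - comm
    else:
        uniq = np.array([config.uniqueness[v] for v in OBSERVED_VARS])
    factors = rng.standard_normal((n, len(FACTOR_NAMES)))
    observed_z = factors @ L.T + rng.standard_normal((n, len(OBSERVED_VARS))) * np.sqrt(uniq)
    obs = pd.DataFrame(observed_z, columns=list(OBSERVED_VARS))

    natural = pd.DataFrame(index=obs.index)
    for var in OBSERVED_VARS:
        loc, scale = NATURAL_SCALES[var]
        natural[var] = loc + scale * obs[var]

    param_cols = ["v6", "v12", "v24", "v48", "a", "t_nd", "s_t", "s_z", "s_v"]
    raw = natural[param_cols]
    clipped = raw.apply(_clip_params, axis=1)
    n_clipped = int((~np.isclose(raw.to_numpy(), clipped.to_numpy())).sum())
    true_params = clipped

    # reading skill
    w = np.asarray(config.reading_weights, dtype=float)
    if config.reading_mode == "factors":
        signal = factors @ w
        for var, dw in config.reading_direct_weights.items():
            signal = signal + dw * obs[var].to_numpy()
        var_signal = float(w @ w) + sum(
            dw**2 for dw in config.reading_direct_weights.values()
        )
    else:
        pa_z = obs[["elision", "blending", "sound_matching"]].mean(axis=1).to_numpy()
        pa_z = (pa_z - pa_z.mean()) / pa_z.std()
        signal = config.mediated_weight * pa_z
        var_signal = config.mediated_weight**2
    noise_sd = (
        config.reading_noise_sd
        if config.reading_noise_sd is not None
        else float(np.sqrt(max(1.0 - var_signal, 0.05)))
    )
    reading_z = signal + noise_sd * rng.standard_normal(n)

    scores = pd.DataFrame({"subject_id": [f"s2_{i:04d}" for i in range(n)]})
    for var in OBSERVED_VARS:
        if var not in param_cols:
            scores[var] = natural[var]
    scores["ctopp_pa"] = 100.0 + 15.0 * obs[["elision", "blending", "sound_matching"]].mean(axis=1)
    scores["ctopp_ran"] = 100.0 + 15.0 * obs[["rapid_digits", "rapid_letters"]].mean(axis=1)
    scores["ctopp_pm"] = 100.0 + 15.0 * obs["nonword_rep"]
    # two reading tests share the latent reading signal plus small test noise
    scores["wj_brs"] = 100.0 + 15.0 * reading_z + rng.normal(0, 3.0, n)
    scores["towre_index"] = 100.0 + 15.0 * reading_z + rng.normal(0, 3.0, n)
    scores["age"] = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    scores["adhd"] = rng.random(n) < config.adhd_rate
    scores["prior_diagnosis"] = False
    scores.attrs["n_clipped"] = n_clipped

    true_params = true_params.copy()
    true_params.insert(0, "subject_id", scores["subject_id"])
    factors_df = pd.DataFrame(factors, columns=list(FACTOR_NAMES))
    factors_df.insert(0, "subject_id", scores["subject_id"])
    factors_df["reading_z"] = reading_z

    trials = None
    if simulate:
        design = {c: config.trials_per_coherence for c in ANALYSIS_COHERENCES}
        frames = []
        child_seeds = ss.spawn(n)
        for i in range(n):
            p = DDMParameters(**{c: float(true_params.iloc[i][c]) for c in param_cols})
            extra = None
            if config.include_100:
                design_i = dict(design)
                design_i[100] = config.trials_per_coherence
                extra = {100: 1.25 * p.v48}
            else:
                design_i = design
            sub_seed = int(child_seeds[i].generate_state(1)[0] % (2**31 - 1))
            t = simulate_trials(p, design_i, seed=sub_seed, extra_drifts=extra)
            t.insert(0, "subject_id", scores["subject_id"].iloc[i])
            frames.append(t)
        trials = pd.concat(frames, ignore_index=True)
        trials["block"] = (trials.groupby("subject_id").cumcount() // 50) + 1

    return Study2Cohort(scores=scores, true_params=true_params, factors=factors_df,
                        trials=trials, config=config)


# ---------------------------------------------------------------------------
# Exclusion-accounting demo cohort


def make_exclusion_demo_cohort(
    seed: int,
    n_total: int = 119,
    n_incomplete: int = 5,
    n_at_chance: int = 2,
    n_over_window: int = 6,
) -> pd.DataFrame:
    """Trial table with planted, disjoint subject-level rule violations.

    Lightweight (non-DDM) trial generation: good subjects perform above
    chance at every coherence with ~2% out-of-window responses; the planted
    violators respectively produce short sessions, 50% accuracy everywhere,
    and ~20% out-of-window responses.
    """
    if n_incomplete + n_at_chance + n_over_window > n_total:
        raise ValueError("violation counts exceed cohort size")
    rng = np.random.default_rng(seed)
    acc_by_coh = {6: 0.66, 12: 0.80, 24: 0.91, 48: 0.97, 100: 0.90}
    frames = []
    kinds = (["incomplete"] * n_incomplete + ["at_chance"] * n_at_chance
             + ["window"] * n_over_window)
    kinds += ["good"] * (n_total - len(kinds))
    for i, kind in enumerate(kinds):
        n_per = 40 if kind == "incomplete" else 60
        rows = []
        for coh in (6, 12, 24, 48, 100):
            # 0.42 keeps the at-chance subjects safely under the 60.5% cut at
            # every coherence even with binomial noise at n=60
            p = 0.42 if kind == "at_chance" else acc_by_coh[coh]
            correct = rng.random(n_per) < p
            frac_fast = 0.22 if kind == "window" else 0.02
            rt = np.clip(rng.lognormal(np.log(0.8), 0.35, n_per), 0.25, 9.5)
            fast = rng.random(n_per) < frac_fast
            rt[fast] = rng.uniform(0.05, 0.15, fast.sum())
            rows.append(pd.DataFrame({
                "subject_id": f"demo_{i:03d}", "coherence": coh,
                "correct": correct, "rt": rt,
            }))
        frames.append(pd.concat(rows, ignore_index=True))
    return pd.concat(frames, ignore_index=True)
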