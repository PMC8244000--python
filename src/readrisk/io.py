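"""CSV schemas, configuration, and the end-to-end pipeline.

Trial CSVs use columns ``subject_id, block, coherence_pct, response,
correct, rt_ms`` (RT in milliseconds on disk, seconds in memory). Score
CSVs carry one row per subject. Every stage of :func:`run_pipeline` draws
its seed deterministically from the global seed, and a JSON manifest
records seeds, input hashes and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddm import DESIGN_COHERENCES, FitConfig, fit_subject

TRIAL_COLUMNS = ["subject_id", "block", "coherence_pct", "response", "correct", "rt_ms"]
SCHEMA_VERSION = "1"


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV into the internal schema (rt in seconds).

    Unknown coherence values and non-numeric RTs are rejected with the
    offending rows named.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path} is missing column(s): {missing}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = rt.isna() & df["rt_ms"].notna()
    if bad_rt.any():
        lines = (df.index[bad_rt] + 2).tolist()[:10]
        raise ValueError(f"non-numeric rt_ms in {path} at line(s) {lines}")
    bad_coh = ~df["coherence_pct"].isin(DESIGN_COHERENCES)
    if bad_coh.any():
        vals = sorted(df.loc[bad_coh, "coherence_pct"].unique().tolist())
        raise ValueError(
            f"coherence values outside the design set {DESIGN_COHERENCES}: {vals}")
    out = pd.DataFrame({
        "subject_id": df["subject_id"].astype(str),
        "block": df["block"].astype(int),
        "coherence": df["coherence_pct"].astype(int),
        "correct": df["correct"].astype(int).astype(bool),
        "rt": rt.astype(float) / 1000.0,
    })
    if "response" in df.columns:
        out["response"] = df["response"]
    return out


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write internal trials to the on-disk CSV schema (rt in ms)."""
    df = pd.DataFrame({
        "subject_id": trials["subject_id"],
        "block": trials.get("block", 1),
        "coherence_pct": trials["coherence"].astype(int),
        "response": trials.get("response", np.where(trials["correct"], "signal", "foil")),
        "correct": trials["correct"].astype(int),
        "rt_ms": (trials["rt"] * 1000.0).round(4),
    })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# readrisk trial schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# readrisk score schema v{SCHEMA_VERSION}\n")
        scores.to_csv(fh, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; stage seeds derive from ``seed``."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # generation (used when no input paths are given)
    generate: bool = True
    n_subjects_study2: int = 40
    trials_per_coherence: int = 60
    study1: bool = True
    study2: bool = True
    efa: bool = True
    fit_ddm: bool = True
    fit_config: FitConfig = field(default_factory=FitConfig)
    # optional external inputs
    trials_path: str | None = None
    scores_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fit_raw = raw.pop("fit_config", None)
        cfg = cls(**raw)
        if fit_raw:
            cfg.fit_config = FitConfig(**fit_raw)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate (optionally) -> preprocess -> fit -> analyze; returns the manifest.

    Any stage error aborts with the stage name; partial outputs and the
    manifest written so far are persisted.
    """
    from . import cohort, efa as efa_mod, preprocess, study1 as s1, study2 as s2

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ["study1", "study2_cohort", "efa", "lasso"], ss.spawn(4))
    }
    manifest: dict = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": {},
        "inputs": {},
    }

    def _save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "setup"
    try:
        # ---------------- study 1
        if config.study1:
            stage = "study1"
            df1 = cohort.generate_study1_cohort(cohort.Study1Config(), stage_seeds["study1"])
            write_scores(df1, out / "study1_scores.csv")
            rep = s1.qda_loo(df1[["pa", "ran"]], df1["diagnosis"], positive_label=True)
            d_pa = s1.cohens_d_disattenuated(
                df1.loc[~df1.diagnosis, "pa"], df1.loc[df1.diagnosis, "pa"], 0.86)
            d_ran = s1.cohens_d_disattenuated(
                df1.loc[~df1.diagnosis, "ran"], df1.loc[df1.diagnosis, "ran"], 0.87)
            manifest["stages"]["study1"] = {
                "n": rep.n,
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "d_pa": d_pa, "d_ran": d_ran,
            }
            (out / "study1_report.json").write_text(json.dumps({
                "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy_ci_halfwidth": rep.accuracy_ci_halfwidth,
                "confusion": rep.confusion,
            }, indent=2))
            _save_manifest()

        # ---------------- study 2 generation + preprocessing
        trials = scores = None
        if config.trials_path and config.scores_path:
            stage = "load"
            trials = read_trials(config.trials_path)
            scores = read_scores(config.scores_path)
            manifest["inputs"] = {
                "trials": _sha256(Path(config.trials_path)),
                "scores": _sha256(Path(config.scores_path)),
            }
            truth = None
        elif config.generate:
            stage = "generate"
            cfg2 = cohort.Study2Config(
                n_subjects=config.n_subjects_study2,
                trials_per_coherence=config.trials_per_coherence,
            )
            coh2 = cohort.generate_study2_cohort(cfg2, stage_seeds["study2_cohort"])
            trials, scores, truth = coh2.trials, coh2.scores, coh2.true_params
            write_trials(trials, out / "study2_trials.csv")
            write_scores(scores, out / "study2_scores.csv")
            write_scores(truth, out / "study2_true_params.csv")
            manifest["stages"]["generate"] = {
                "n_subjects": int(scores.shape[0]), "n_trials": int(trials.shape[0]),
            }
            _save_manifest()

        if trials is None:
            _save_manifest()
            return manifest

        stage = "preprocess"
        flagged = preprocess.flag_valid_trials(trials)
        designed = 5 * config.trials_per_coherence
        kept, report = preprocess.apply_subject_exclusions(flagged, designed_trials=designed)
        analysis = preprocess.drop_excluded_coherence(kept)
        analysis = analysis[analysis["valid"]]
        scores = preprocess.compute_reading_group(scores)
        scores = scores[scores["subject_id"].isin(kept["subject_id"].unique())]
        (out / "exclusion_report.json").write_text(json.dumps(report, indent=2, default=str))
        manifest["stages"]["preprocess"] = {
            k: report[k] for k in
            ("n_subjects_in", "excluded_incomplete", "excluded_at_chance",
             "excluded_window", "n_subjects_retained")
        }
        _save_manifest()

        stage = "rt_summaries"
        medians = preprocess.cohort_rt_summaries(analysis)
        medians = medians.merge(
            scores[["subject_id", "age", "reading_composite"]], on="subject_id")
        medians = medians.rename(columns={"reading_composite": "reading"})
        medians.to_csv(out / "rt_summaries.csv", index=False)
        rt_model = s2.fit_median_rt_model(medians)
        manifest["stages"]["rt_model"] = {
            "singular": rt_model["singular"],
            "coefficients": rt_model["table"].table.to_dict("records"),
        }
        _save_manifest()

        # ---------------- DDM fitting
        stage = "fit_ddm"
        if config.fit_ddm:
            fit_rows = []
            fit_seeds = ss.spawn(scores.shape[0])
            for (sid, sub), fseed in zip(analysis.groupby("subject_id", sort=True), fit_seeds):
                res = fit_subject(sub, config=config.fit_config,
                                  seed=int(fseed.generate_state(1)[0] % (2**31 - 1)))
                fit_rows.append({
                    "subject_id": sid, **res.params.to_dict(), "nll": res.nll,
                    "converged": res.converged, "n_trials_used": res.n_trials_used,
                })
            fits = pd.DataFrame(fit_rows)
            write_scores(fits, out / "ddm_fits.csv")
            manifest["stages"]["fit_ddm"] = {
                "n_fit": len(fits), "n_converged": int(fits["converged"].sum()),
            }
        elif truth is not None:
            fits = truth.copy()
        else:
            fits = None
        _save_manifest()

        # ---------------- study 2 models + EFA
        if config.study2 and fits is not None:
            stage = "study2"
            comp = s2.build_composites(fits)
            merged = comp.merge(scores, on="subject_id")
            merged["reading"] = merged["reading_composite"]
            add = s2.additive_model_selection(merged)
            merged["mean_drift"] = s2.mean_drift(
                fits.set_index("subject_id").loc[merged["subject_id"]].reset_index())
            (out / "additive_model.json").write_text(json.dumps({
                "selected_terms": add["selected_terms"],
                "ddm_block_retained": add["ddm_block_retained"],
                "f_test": add["f_test"],
                "aic_selected": add["selected"].aic, "bic_selected": add["selected"].bic,
                "aic_reduced": add["reduced"].aic, "bic_reduced": add["reduced"].bic,
            }, indent=2))
            add["selected"].table.to_csv(out / "additive_model_coefficients.csv", index=False)
            manifest["stages"]["study2"] = {
                "selected_terms": add["selected_terms"],
                "f_test_p": add["f_test"]["p"],
            }
            _save_manifest()

        if config.efa and fits is not None:
            stage = "efa"
            Xvars = fits.set_index("subject_id")[
                ["v6", "v12", "v24", "v48", "s_v", "s_t", "t_nd", "s_z", "a"]]
            score_vars = scores.set_index("subject_id")[
                ["elision", "blending", "sound_matching", "nonword_rep",
                 "nonverbal_iq", "rapid_digits", "rapid_letters"]]
            X = Xvars.join(score_vars, how="inner")
            ret = efa_mod.retain_factors(X, n_sim=200, seed=stage_seeds["efa"])
            k = max(ret["k"], 1)
            fm = efa_mod.efa_varimax(X, k)
            fm.loadings.to_csv(out / "efa_loadings.csv")
            reading = scores.set_index("subject_id").loc[X.index, "reading_composite"]
            loo = efa_mod.factor_loocv_prediction(fm.scores, reading)
            manifest["stages"]["efa"] = {
                "k_parallel": ret["k"], "k_kaiser": ret["kaiser"],
                "explained_variance_total": fm.explained_variance_total,
                **{key: val for key, val in loo.items() if key != "single_factor"},
                "single_factor": loo["single_factor"],
            }
            _save_manifest()

        manifest["status"] = "ok"
        _save_manifest()
        return manifest
    except Exception as err:
        manifest["status"] = "error"
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _save_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
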