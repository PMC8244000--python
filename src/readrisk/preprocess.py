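"""Trial- and subject-level screening, reading composites, and RT summaries.

Implements the screening pipeline for the motion-discrimination sessions:
an acceptable response window of 200 ms to 10 s, subject-level exclusion of
incomplete sessions / at-chance performers / subjects with too many
out-of-window responses, removal of the non-monotonic 100% coherence
condition, and the reading-composite group labels (composite < 85 defines
the dyslexic range).

Trial tables are pandas DataFrames with at least columns
``subject_id, coherence, correct, rt`` (rt in seconds); score tables carry
one row per subject.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ddm import ANALYSIS_COHERENCES

#: Acceptable response-time window in seconds, endpoints inclusive.
RT_WINDOW = (0.2, 10.0)
#: A subject must exceed this accuracy at >= 1 analysis coherence.
CHANCE_ACCURACY_CUTOFF = 0.605
#: Maximum tolerated fraction of out-of-window responses per subject.
MAX_INVALID_FRACTION = 0.15
#: Designed session length (60 trials x 5 coherence levels).
DESIGNED_TRIALS = 300
#: Reading composite below this standard score defines the dyslexic range.
READING_CUTOFF = 85.0


def flag_valid_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a boolean ``valid`` column for the RT window.

    Rows with non-positive RT are malformed records: they are dropped with a
    warning rather than merely flagged.
    """
    out = trials.copy()
    bad = out["rt"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} records with non-positive RT", stacklevel=2)
        out = out[~bad].copy()
    out["valid"] = (out["rt"] >= RT_WINDOW[0]) & (out["rt"] <= RT_WINDOW[1])
    return out


def apply_subject_exclusions(
    trials: pd.DataFrame,
    designed_trials: int = DESIGNED_TRIALS,
) -> tuple[pd.DataFrame, dict]:
    """Apply the three subject-level exclusion rules in order.

    (i) incomplete sessions (fewer than ``designed_trials`` rows), then
    (ii) at-chance performance (accuracy <= 60.5% at every analysis
    coherence), then (iii) more than 15% of trials outside the RT window.
    Each subject is counted against the first rule it violates.

    Returns the retained trials and a report with per-rule counts.
    """
    report = {
        "n_subjects_in": 0,
        "excluded_incomplete": 0,
        "excluded_at_chance": 0,
        "excluded_window": 0,
        "n_subjects_retained": 0,
        "excluded_ids": {},
    }
    if len(trials) == 0:
        report["excluded_ids"] = {"incomplete": [], "at_chance": [], "window": []}
        return trials.copy(), report
    if "valid" not in trials.columns:
        trials = flag_valid_trials(trials)

    excluded: dict[str, list] = {"incomplete": [], "at_chance": [], "window": []}
    keep = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        if len(sub) < designed_trials:
            excluded["incomplete"].append(sid)
            continue
        analysis = sub[sub["coherence"].isin(ANALYSIS_COHERENCES)]
        acc = analysis.groupby("coherence")["correct"].mean()
        if not (acc > CHANCE_ACCURACY_CUTOFF).any():
            excluded["at_chance"].append(sid)
            continue
        if (~sub["valid"]).mean() > MAX_INVALID_FRACTION:
            excluded["window"].append(sid)
            continue
        keep.append(sid)

    report["n_subjects_in"] = trials["subject_id"].nunique()
    report["excluded_incomplete"] = len(excluded["incomplete"])
    report["excluded_at_chance"] = len(excluded["at_chance"])
    report["excluded_window"] = len(excluded["window"])
    report["n_subjects_retained"] = len(keep)
    report["excluded_ids"] = excluded
    return trials[trials["subject_id"].isin(keep)].copy(), report


def drop_excluded_coherence(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove the 100% coherence condition, keeping the monotonic 6-48% range."""
    if len(trials) == 0:
        return trials.copy()
    return trials[trials["coherence"] != 100].copy()


def compute_reading_group(scores: pd.DataFrame) -> pd.DataFrame:
    """Add ``reading_composite`` and ``group_label`` columns.

    The composite is the mean of the two standardized reading measures
    (WJ basic reading and TOWRE index). Label ``Dyslexic`` when the composite
    is below 85; ``Control`` when at/above 85 with no prior diagnosis;
    otherwise ``Unlabeled`` (including missing scores).
    """
    out = scores.copy()
    prior = out["prior_diagnosis"] if "prior_diagnosis" in out.columns else pd.Series(
        False, index=out.index)
    composite = out[["wj_brs", "towre_index"]].mean(axis=1, skipna=False)
    out["reading_composite"] = composite
    label = np.where(
        composite.isna(), "Unlabeled",
        np.where(composite < READING_CUTOFF, "Dyslexic",
                 np.where(~prior.fillna(False).astype(bool), "Control", "Unlabeled")),
    )
    out["group_label"] = label
    n_missing = int(composite.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} subjects missing a reading score; labeled Unlabeled",
                      stacklevel=2)
    return out


def rt_summaries(trials: pd.DataFrame) -> dict:
    """Per-coherence median RT and accuracy plus the fast-error ratio.

    For one subject's valid analysis trials. The fast-error ratio is
    median(correct RT) / median(error RT), pooled across coherences; values
    above 1 are the fast-error signature of starting-point variability. The
    ratio is NaN when the subject made no errors (flagged in the output).
    """
    per = (
        trials.groupby("coherence")
        .agg(median_rt=("rt", "median"), accuracy=("correct", "mean"), n=("rt", "size"))
        .reset_index()
    )
    corr_rt = trials.loc[trials["correct"], "rt"]
    err_rt = trials.loc[~trials["correct"], "rt"]
    if len(err_rt) == 0 or len(corr_rt) == 0:
        ratio = float("nan")
    else:
        ratio = float(corr_rt.median() / err_rt.median())
    per_coh_ratio = {}
    for coh, sub in trials.groupby("coherence"):
        c, e = sub.loc[sub["correct"], "rt"], sub.loc[~sub["correct"], "rt"]
        per_coh_ratio[int(coh)] = float(c.median() / e.median()) if len(c) and len(e) else float("nan")
    return {
        "per_coherence": per,
        "fast_error_ratio": ratio,
        "fast_error_ratio_defined": not np.isnan(ratio),
        "per_coherence_ratio": per_coh_ratio,
    }


def cohort_rt_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject-per-coherence medians/accuracy plus fast-error ratios."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        summ = rt_summaries(sub)
        per = summ["per_coherence"].copy()
        per.insert(0, "subject_id", sid)
        per["fast_error_ratio"] = summ["fast_error_ratio"]
        rows.append(per)
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "coherence", "median_rt", "accuracy", "n", "fast_error_ratio"])
    return pd.concat(rows, ignore_index=True)
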