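#!/usr/bin/env python
"""Screen the psychophysics sessions and fit the DDM per subject.

Applies the RT window (200 ms - 10 s), the subject exclusion rules, and the
100%-coherence drop, then fits the 9-parameter drift diffusion model to each
retained subject's 240 analysis trials by penalized maximum likelihood.

Fitting all 106 subjects takes ~10 minutes on one core; pass --n-subjects to
fit a subset while iterating.

Reads results/cohorts/, writes results/ddm/.
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from readrisk.ddm import fit_subject
from readrisk.io import read_scores, read_trials, write_scores, write_trials
from readrisk.preprocess import (
    apply_subject_exclusions,
    cohort_rt_summaries,
    drop_excluded_coherence,
    flag_valid_trials,
)

IN = Path("results/cohorts")
OUT = Path("results/ddm")
SEED = 314159


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-subjects", type=int, default=None,
                    help="fit only the first N retained subjects")
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    trials = flag_valid_trials(read_trials(IN / "study2_trials.csv"))
    kept, report = apply_subject_exclusions(trials)
    analysis = drop_excluded_coherence(kept)
    analysis = analysis[analysis["valid"]]
    (OUT / "exclusion_report.json").write_text(json.dumps(report, indent=2, default=str))
    print(f"retained {report['n_subjects_retained']}/{report['n_subjects_in']} subjects "
          f"(incomplete={report['excluded_incomplete']}, "
          f"at-chance={report['excluded_at_chance']}, window={report['excluded_window']})")

    summaries = cohort_rt_summaries(analysis)
    summaries.to_csv(OUT / "rt_summaries.csv", index=False)

    subjects = sorted(analysis["subject_id"].unique())
    if args.n_subjects:
        subjects = subjects[: args.n_subjects]
    rows = []
    ss = np.random.SeedSequence(SEED)
    t0 = time.time()
    for sid, child in zip(subjects, ss.spawn(len(subjects))):
        sub = analysis[analysis["subject_id"] == sid]
        res = fit_subject(sub, seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        rows.append({"subject_id": sid, **res.params.to_dict(), "nll": res.nll,
                     "converged": res.converged, "n_trials_used": res.n_trials_used})
    fits = pd.DataFrame(rows)
    write_scores(fits, OUT / "ddm_fits.csv")
    print(f"fit {len(fits)} subjects in {time.time() - t0:.0f}s; "
          f"{int(fits['converged'].sum())} converged")
    print(fits[["v6", "v12", "v24", "v48", "a", "t_nd"]].describe().loc[["mean", "std"]].round(2))


if __name__ == "__main__":
    main()
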