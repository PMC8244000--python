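#!/usr/bin/env python
"""Generate the two synthetic cohorts all downstream analyses consume.

Cohort 1 emulates a large clinic-referred sample: two diagnosis groups
separated by ~0.9 SD on phonological awareness and ~0.8 SD on rapid naming.
Cohort 2 emulates the in-lab psychophysics study: 106 children with a
planted four-factor structure (visual encoding, phonology+IQ, rapid naming,
decision variability) behind their DDM parameters and behavioral scores,
plus a full 300-trial motion-discrimination session simulated per subject.

Writes results/cohorts/.
"""

from pathlib import Path

from readrisk.cohort import Study1Config, Study2Config, generate_study1_cohort, generate_study2_cohort
from readrisk.io import write_scores, write_trials

OUT = Path("results/cohorts")
SEED = 20231107


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    df1 = generate_study1_cohort(Study1Config(), seed=SEED)
    write_scores(df1, OUT / "study1_scores.csv")
    print(f"study 1: {len(df1)} subjects "
          f"({int(df1.diagnosis.sum())} diagnosed, {int((~df1.diagnosis).sum())} controls)")

    coh = generate_study2_cohort(Study2Config(), seed=SEED + 1)
    write_trials(coh.trials, OUT / "study2_trials.csv")
    write_scores(coh.scores, OUT / "study2_scores.csv")
    write_scores(coh.true_params, OUT / "study2_true_params.csv")
    write_scores(coh.factors, OUT / "study2_true_factors.csv")
    print(f"study 2: {coh.scores.shape[0]} subjects, {len(coh.trials)} trials "
          f"({coh.scores.attrs['n_clipped']} parameter values clipped into the valid region)")


if __name__ == "__main__":
    main()
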