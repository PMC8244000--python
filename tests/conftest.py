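import numpy as np
import pandas as pd
import pytest

from readrisk.cohort import Study2Config, generate_study2_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture(scope="session")
def study2_cohort_noim():
    """Mid-sized planted-structure cohort without trial simulation."""
    return generate_study2_cohort(Study2Config(n_subjects=200), seed=42, simulate=False)


@pytest.fixture(scope="session")
def merged_study2(study2_cohort_noim):
    """Scores + true parameters + composites merged, with a reading column."""
    from readrisk.study2 import build_composites, mean_drift

    coh = study2_cohort_noim
    comp = build_composites(coh.true_params)
    merged = comp.merge(coh.scores, on="subject_id")
    merged["reading"] = merged[["wj_brs", "towre_index"]].mean(axis=1)
    merged["mean_drift"] = mean_drift(coh.true_params)
    return merged


def make_trials(rts, correct=None, coherence=12, subject_id="s"):
    """Small helper for hand-built trial tables."""
    rts = np.asarray(rts, dtype=float)
    if correct is None:
        correct = np.ones(len(rts), dtype=bool)
    return pd.DataFrame({
        "subject_id": subject_id,
        "coherence": coherence,
        "correct": np.asarray(correct, dtype=bool),
        "rt": rts,
    })
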