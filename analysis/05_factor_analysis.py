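#!/usr/bin/env python
"""How many latent dimensions explain the measure battery?

Exploratory factor analysis over the 9 DDM parameters, the six phonological
subtests, and nonverbal IQ: retention by eigenvalues > 1 and parallel
analysis, maximum-likelihood extraction with varimax rotation, and a
leave-one-out comparison of reading-skill prediction from all retained
factors versus the single best factor.

Reads results/cohorts/ and results/ddm/, writes results/efa/.
"""

import json
from pathlib import Path

import pandas as pd

from readrisk.efa import efa_varimax, factor_loocv_prediction, retain_factors
from readrisk.io import read_scores

COHORTS = Path("results/cohorts")
DDM = Path("results/ddm")
OUT = Path("results/efa")
SEED = 16180
PARAM_COLS = ["v6", "v12", "v24", "v48", "s_v", "s_t", "t_nd", "s_z", "a"]
SCORE_COLS = ["elision", "blending", "sound_matching", "nonword_rep",
              "nonverbal_iq", "rapid_digits", "rapid_letters"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fits_path = DDM / "ddm_fits.csv"
    params = read_scores(fits_path if fits_path.exists()
                         else COHORTS / "study2_true_params.csv")
    scores = read_scores(COHORTS / "study2_scores.csv")
    X = params.set_index("subject_id")[PARAM_COLS].join(
        scores.set_index("subject_id")[SCORE_COLS], how="inner")

    ret = retain_factors(X, n_sim=1000, seed=SEED)
    print(f"eigenvalues > 1: {ret['kaiser']}; parallel analysis retains {ret['k']}")
    pd.DataFrame({"eigenvalue": ret["eigenvalues"],
                  "parallel_95pct": ret["thresholds"]}).to_csv(OUT / "scree.csv",
                                                               index=False)

    k = max(ret["k"], 1)
    fm = efa_varimax(X, k)
    fm.loadings.round(3).to_csv(OUT / "loadings.csv")
    print(f"{k}-factor varimax solution explains "
          f"{fm.explained_variance_total:.1%} of total variance "
          f"({', '.join(f'{v:.1%}' for v in fm.explained_variance)})")
    print(f"unexplained variance in a: {fm.uniquenesses['a']:.0%}")

    reading = scores.set_index("subject_id")[["wj_brs", "towre_index"]].mean(axis=1)
    loo = factor_loocv_prediction(fm.scores, reading.loc[X.index])
    print(f"LOO-CV reading prediction: {k}-factor R2 = {loo['r2_loo_full']:.1%}, "
          f"single-factor ({loo['single_factor']}) R2 = {loo['r2_loo_single']:.1%}")

    report = {
        "k_kaiser": ret["kaiser"], "k_parallel": ret["k"],
        "explained_variance_total": fm.explained_variance_total,
        "explained_variance": fm.explained_variance.to_dict(),
        "uniqueness_a": float(fm.uniquenesses["a"]),
        "heywood": fm.heywood,
        **loo,
    }
    (OUT / "efa_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
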