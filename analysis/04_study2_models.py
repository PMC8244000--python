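#!/usr/bin/env python
"""Model reading skill from DDM parameters and phonology.

The sequence: median-RT mixed model (does task performance track reading at
all?), per-parameter models with AIC selection, the parameter
correlation/cluster structure (drifts + s_v cluster together; s_t, t_nd and
s_z form a second block; a stands alone), PC1 composites v_comp and d_comp,
the additive model of reading skill with the nested F-test against a
phonology-only model, lasso confirmation, mediation by PA, and the high-PA
subgroup analysis.

Reads results/cohorts/ and results/ddm/, writes results/study2/.
Uses fitted parameters when 03 produced a full set, otherwise the
generator's true parameters (noted in the output).
"""

import json
from pathlib import Path

import pandas as pd

from readrisk.io import read_scores
from readrisk.preprocess import compute_reading_group
from readrisk.study2 import (
    additive_model_selection,
    build_composites,
    fit_median_rt_model,
    fit_parameter_model,
    lasso_cv,
    mean_drift,
    mediation_analysis,
    parameter_correlation_structure,
    subgroup_analysis,
)

COHORTS = Path("results/cohorts")
DDM = Path("results/ddm")
OUT = Path("results/study2")
SEED = 271828
PARAM_COLS = ["v6", "v12", "v24", "v48", "a", "t_nd", "s_t", "s_z", "s_v"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scores = compute_reading_group(read_scores(COHORTS / "study2_scores.csv"))
    scores["reading"] = scores["reading_composite"]

    fits_path = DDM / "ddm_fits.csv"
    if fits_path.exists():
        fits = read_scores(fits_path)
        source = "fitted"
    else:
        fits = read_scores(COHORTS / "study2_true_params.csv")
        source = "generator-truth"
    fits = fits[fits["subject_id"].isin(scores["subject_id"])]
    scores = scores[scores["subject_id"].isin(fits["subject_id"])]
    print(f"parameter source: {source} ({len(fits)} subjects)")

    # median RT mixed model
    med = read_scores(DDM / "rt_summaries.csv") if (DDM / "rt_summaries.csv").exists() else None
    if med is not None:
        med = med.merge(scores[["subject_id", "age", "reading"]], on="subject_id")
        rt_out = fit_median_rt_model(med)
        rt_out["table"].table.to_csv(OUT / "median_rt_model.csv", index=False)
        coef = rt_out["table"].table.set_index("term")
        print("median RT model: coherence beta "
              f"{coef.loc['z_coherence', 'beta']:.3f} (p={coef.loc['z_coherence', 'p']:.2g}), "
              f"reading beta {coef.loc['z_reading', 'beta']:.3f}")

    # per-parameter models
    merged = fits.merge(scores, on="subject_id")
    per_param = {}
    for param in ("s_z", "a", "t_nd", "s_t"):
        tab = fit_parameter_model(merged, param)
        retained = param in set(tab.table["term"])
        per_param[param] = {
            "retained": retained,
            "partial_r2": tab.partial_r2.get(param),
            "coefficients": tab.table.to_dict("records"),
        }
        print(f"reading ~ {param}: retained={retained}, "
              f"partial r2={tab.partial_r2.get(param)}")
    (OUT / "per_parameter_models.json").write_text(json.dumps(per_param, indent=2))

    # correlation structure and clusters
    struct = parameter_correlation_structure(fits[PARAM_COLS])
    struct["correlations"].to_csv(OUT / "parameter_correlations.csv")
    struct["clusters"].to_csv(OUT / "parameter_clusters.csv")
    print("parameter clusters:", struct["clusters"].to_dict())

    # composites + additive model
    comp = build_composites(fits)
    data = comp.merge(scores, on="subject_id")
    data["reading"] = data["reading_composite"]
    add = additive_model_selection(data)
    add["selected"].table.to_csv(OUT / "additive_model.csv", index=False)
    print(f"additive model selected terms: {add['selected_terms']}")
    print(f"DDM block F({add['f_test']['df_num']:.0f}, "
          f"{add['f_test']['df_resid_full']:.0f}) = {add['f_test']['F']:.2f}, "
          f"p = {add['f_test']['p']:.4g}; "
          f"AIC selected {add['selected'].aic:.1f} vs reduced {add['reduced'].aic:.1f}")

    # lasso confirmation
    X = data[["v_comp", "d_comp", "a", "ctopp_pa", "ctopp_ran", "nonverbal_iq",
              "age"]].assign(adhd=data["adhd"].astype(float))
    las = lasso_cv(X, data["reading"], seed=SEED)
    print("lasso support:", las["support"])

    # mediation of the drift-reading path by PA
    data["mean_drift"] = mean_drift(fits)
    med_out = mediation_analysis(data, "v_comp", "ctopp_pa", "reading",
                                 n_boot=2000, seed=SEED)
    print(f"mediation: indirect {med_out['indirect']:.3f} CI {med_out['indirect_ci']}, "
          f"direct {med_out['direct']:.3f} CI {med_out['direct_ci']}")

    # high-PA subgroup
    sub = subgroup_analysis(data, "ctopp_pa", 100.0)
    print(f"high-PA subgroup (n={sub['n']}): r(reading, mean drift) = {sub['r']:.2f}, "
          f"p = {sub['p']:.3g}")

    summary = {
        "parameter_source": source,
        "selected_terms": add["selected_terms"],
        "ddm_block_retained": add["ddm_block_retained"],
        "f_test": add["f_test"],
        "aic": {"selected": add["selected"].aic, "reduced": add["reduced"].aic},
        "bic": {"selected": add["selected"].bic, "reduced": add["reduced"].bic},
        "lasso_support": las["support"],
        "mediation": {k: med_out[k] for k in
                      ("indirect", "indirect_ci", "direct", "direct_ci",
                       "proportion_mediated")},
        "high_pa_subgroup": {"n": sub["n"], "r": sub["r"], "p": sub["p"]},
        "clusters": struct["clusters"].to_dict(),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, default=str))


if __name__ == "__main__":
    main()
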