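"""Drift diffusion model: densities, simulator, likelihood, and fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid, quad

from readrisk import ddm
from readrisk.ddm import (
    ANALYSIS_COHERENCES,
    DDMParameters,
    FitConfig,
    choice_probability,
    fit_subject,
    fpt_density,
    full_fpt_density,
    negative_log_likelihood,
    simulate_trials,
)

from conftest import make_trials


BASE = dict(v6=0.8, v12=1.5, v24=2.5, v48=3.5, a=1.3, t_nd=0.45,
            s_t=0.2, s_z=0.2, s_v=0.6)


# ---------------------------------------------------------------------------
# choice probability


def test_choice_probability_values():
    assert choice_probability(0.0, 1.0) == pytest.approx(0.5)
    # closed-form absorption probability
    assert choice_probability(1.0, 2.0) == pytest.approx(0.8808, abs=1e-4)
    assert choice_probability(10.0, 2.0) > 0.999


def test_choice_probability_monotone_in_v_and_a():
    ps = [choice_probability(v, 1.5) for v in np.linspace(0.1, 4, 12)]
    assert all(x < y for x, y in zip(ps, ps[1:]))
    pa = [choice_probability(1.0, a) for a in np.linspace(0.5, 3, 12)]
    assert all(x < y for x, y in zip(pa, pa[1:]))


def test_choice_probability_domain_errors():
    with pytest.raises(ValueError):
        choice_probability(1.0, -1.0)
    with pytest.raises(ValueError):
        choice_probability(1.0, 1.0, z_rel=1.5)


# ---------------------------------------------------------------------------
# first-passage densities


def test_fpt_density_zero_before_zero_time():
    assert fpt_density(1.0, 1.0, 0.5, -0.5) == 0.0
    assert fpt_density(1.0, 1.0, 0.5, 0.0) == 0.0


def test_fpt_density_zero_drift_symmetry():
    for t in (0.05, 0.2, 0.8, 2.0):
        c = fpt_density(0.0, 1.2, 0.5, t, "correct")
        e = fpt_density(0.0, 1.2, 0.5, t, "error")
        assert c == pytest.approx(e, rel=1e-10)


@pytest.mark.parametrize("v,a,z", [(1.2, 1.3, 0.5), (0.3, 0.8, 0.5), (2.5, 2.0, 0.3)])
def test_fpt_density_integrates_to_choice_probability(v, a, z):
    m_c = quad(lambda t: fpt_density(v, a, z, t, "correct"), 0, 60, limit=300)[0]
    m_e = quad(lambda t: fpt_density(v, a, z, t, "error"), 0, 60, limit=300)[0]
    assert m_c + m_e == pytest.approx(1.0, abs=1e-6)
    assert m_c == pytest.approx(choice_probability(v, a, z), abs=1e-6)


def test_full_density_degenerate_support():
    p = DDMParameters(1.0, 1.0, 1.0, 1.0, a=1.0, t_nd=0.4)
    assert full_fpt_density(p, 6, 0.3) == 0.0  # before t_nd
    # reduces exactly to the shifted simple density
    t = 0.9
    assert full_fpt_density(p, 6, t) == pytest.approx(
        fpt_density(1.0, 1.0, 0.5, t - 0.4), rel=1e-12)


def test_full_density_mass_conservation():
    p = DDMParameters(**BASE)
    for coh in (6, 48):
        m_c = quad(lambda t: full_fpt_density(p, coh, t, "correct"), 0, 60, limit=400)[0]
        m_e = quad(lambda t: full_fpt_density(p, coh, t, "error"), 0, 60, limit=400)[0]
        assert m_c + m_e == pytest.approx(1.0, abs=1e-4)


def test_full_density_matches_simulated_histogram():
    """Analytic full density tracks a simulated RT histogram at a parameter
    set with all variabilities active."""
    p = DDMParameters(v6=1.5, v12=1.5, v24=1.5, v48=1.5, a=1.2, t_nd=0.4,
                      s_t=0.2, s_z=0.3 * 1.2, s_v=0.5)
    trials = simulate_trials(p, {12: 100000}, seed=99)
    corr = trials[trials["correct"]]
    edges = np.linspace(0.3, 3.0, 28)
    hist, _ = np.histogram(corr["rt"], bins=edges, density=True)
    hist *= len(corr) / len(trials)  # to defective-density scale
    # bin-averaged analytic density via the CDF (the curve is steep near
    # the mode, so bin-center evaluation would bias the comparison)
    fine = np.linspace(edges[0], edges[-1], 40 * (len(edges) - 1) + 1)
    dens_fine = full_fpt_density(p, 12, fine, "correct")
    cdf = cumulative_trapezoid(dens_fine, fine, initial=0.0)
    cdf_at_edges = np.interp(edges, fine, cdf)
    dens = np.diff(cdf_at_edges) / np.diff(edges)
    # Monte-Carlo tolerance
    np.testing.assert_allclose(hist, dens, atol=0.03)


# ---------------------------------------------------------------------------
# simulator


def test_simulate_empty_design():
    p = DDMParameters(**BASE)
    out = simulate_trials(p, {6: 0, 12: 0}, seed=1)
    assert len(out) == 0


def test_simulate_accuracy_matches_closed_form():
    p = DDMParameters(v6=2.0, v12=2.0, v24=2.0, v48=2.0, a=1.5, t_nd=0.3)
    trials = simulate_trials(p, {24: 200000}, seed=5)
    p_th = choice_probability(2.0, 1.5)
    se = np.sqrt(p_th * (1 - p_th) / len(trials))
    assert abs(trials["correct"].mean() - p_th) < 3 * se


def test_simulate_seed_determinism():
    p = DDMParameters(**BASE)
    a = simulate_trials(p, {6: 50, 24: 50}, seed=3)
    b = simulate_trials(p, {6: 50, 24: 50}, seed=3)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_trials(p, {6: 50, 24: 50}, seed=4)
    assert not np.allclose(a["rt"], c["rt"])


def test_simulate_fast_errors_with_large_sz():
    """Large starting-point variability produces median error RT below
    median correct RT (fast errors)."""
    a = 1.2
    p = DDMParameters(v6=1.5, v12=1.5, v24=1.5, v48=1.5, a=a, t_nd=0.35,
                      s_t=0.0, s_z=0.8 * a, s_v=0.0)
    trials = simulate_trials(p, {12: 100000}, seed=11)
    med_err = trials.loc[~trials["correct"], "rt"].median()
    med_cor = trials.loc[trials["correct"], "rt"].median()
    assert med_err < med_cor


def test_simulate_symmetry_unbiased_no_variability():
    """z_rel=0.5 without variability: correct and error RT distributions
    coincide (classic unbiased-diffusion result)."""
    p = DDMParameters(v6=1.0, v12=1.0, v24=1.0, v48=1.0, a=1.4, t_nd=0.0)
    trials = simulate_trials(p, {12: 300000}, seed=21)
    med_c = trials.loc[trials["correct"], "rt"].median()
    med_e = trials.loc[~trials["correct"], "rt"].median()
    assert abs(med_c - med_e) / med_c < 0.02


def test_simulate_mean_dt_zero_drift():
    """Mean decision time at v=0, z_rel=0.5 is a^2/4 (sigma=1)."""
    p = DDMParameters(v6=0.0, v12=0.0, v24=0.0, v48=0.0, a=1.4, t_nd=0.0)
    trials = simulate_trials(p, {6: 150000}, seed=8)
    assert trials["rt"].mean() == pytest.approx(1.4**2 / 4, rel=0.02)


def test_simulate_rejects_unknown_coherence():
    p = DDMParameters(**BASE)
    with pytest.raises(ValueError, match="design set"):
        simulate_trials(p, {37: 10}, seed=0)


# ---------------------------------------------------------------------------
# likelihood


def test_nll_empty_trials_zero_with_warning():
    p = DDMParameters(**BASE)
    with pytest.warns(UserWarning, match="empty"):
        out = negative_log_likelihood(p, make_trials([]))
    assert out == 0.0


def test_nll_single_trial_is_minus_log_density():
    p = DDMParameters(**BASE)
    t = make_trials([0.9], correct=[True], coherence=24)
    d = full_fpt_density(p, 24, 0.9, "correct")
    assert negative_log_likelihood(p, t) == pytest.approx(-np.log(d), rel=1e-9)


def test_nll_profile_minimum_near_truth():
    """NLL at the generating parameters beats +/-50% drift perturbations."""
    p = DDMParameters(**BASE)
    trials = simulate_trials(p, {c: 2500 for c in ANALYSIS_COHERENCES}, seed=13)
    base_nll = negative_log_likelihood(p, trials)
    for fac in (0.5, 1.5):
        pert = DDMParameters(**{**BASE,
                                **{k: BASE[k] * fac for k in ("v6", "v12", "v24", "v48")}})
        assert negative_log_likelihood(pert, trials) > base_nll


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        DDMParameters(1, 1, 1, 1, a=-1.0, t_nd=0.3).validate()
    with pytest.raises(ValueError):
        DDMParameters(1, 1, 1, 1, a=1.0, t_nd=0.1, s_t=0.4).validate()
    with pytest.raises(ValueError):
        DDMParameters(1, 1, 1, 1, a=1.0, t_nd=0.3, s_z=1.1).validate()


# ---------------------------------------------------------------------------
# fitting


def test_fit_refuses_insufficient_trials():
    p = DDMParameters(**BASE)
    trials = simulate_trials(p, {c: 20 for c in ANALYSIS_COHERENCES}, seed=2)
    with pytest.raises(ValueError, match="insufficient"):
        fit_subject(trials)


def test_fit_degenerate_rts_flagged():
    rows = []
    for c in ANALYSIS_COHERENCES:
        rows.append(make_trials(np.full(45, 0.7), coherence=c))
    trials = pd.concat(rows, ignore_index=True)
    res = fit_subject(trials)
    assert not res.converged
    assert res.diagnostics.get("degenerate_rts")


def test_fit_single_subject_recovery():
    """Point recovery at the task's 240-trial design; tolerances from a
    frozen pilot calibration."""
    true = DDMParameters(**BASE)
    trials = simulate_trials(true, {c: 60 for c in ANALYSIS_COHERENCES}, seed=11)
    res = fit_subject(trials, seed=1)
    assert res.converged
    assert res.n_trials_used == 240
    assert abs(res.params.v24 - true.v24) < 0.5
    assert abs(res.params.a - true.a) < 0.3
    assert abs(res.params.t_nd - true.t_nd) < 0.1


def test_fit_drifts_monotone_in_coherence():
    """Fitted drifts are non-decreasing in coherence for most subjects when
    the truth is increasing."""
    from readrisk.recovery import run_recovery_study

    res = run_recovery_study(n_subjects=10, trials_per_coherence=60, seed=77,
                             monotone_drifts=True)
    rec = res.recovered[["v6", "v12", "v24", "v48"]].to_numpy()
    tol = 0.15  # small estimation-noise slack on near-tied adjacent truths
    mono = ((rec[:, 1:] - rec[:, :-1]) > -tol).all(axis=1)
    assert mono.mean() >= 0.9
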