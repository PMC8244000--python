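# readrisk

Multifactorial modelling of children's reading skill from psychophysics and
phonology.

Competing accounts of developmental dyslexia disagree about whether reading
difficulty stems from a single "core" deficit (usually phonological, with
sensory deficits acting only through a cascade into phonology) or from
several additive risk factors. This package implements the full analytic
machinery needed to adjudicate: (Study 1) how well phonological awareness
(PA) and rapid automatized naming (RAN) classify a dyslexia diagnosis, and
(Study 2) drift-diffusion-model decomposition of a random-dot-motion task
into sensory and non-sensory parameters, followed by additive modelling of
reading skill, correlation/cluster structure, mediation, and exploratory
factor analysis. A synthetic-cohort engine generates data with any planted
structure — additive or cascading — so the whole pipeline is reproducible
and testable without external data. It is intended for researchers in
psycholinguistics and psychophysics who want a tested, scriptable version of
this analysis chain.

## The model

Behaviour on a two-alternative motion task is modelled by the drift
diffusion model (DDM): evidence `x` accumulates from `z = a/2` with drift
`v_c` per coherence `c in {6, 12, 24, 48}%` and unit diffusion until
absorption at `a` (correct) or `0` (error); RT is the first-passage time
plus non-decision time `t_nd`. Across trials, drift ~ Normal(`v_c`,
`s_v`^2), starting point ~ Uniform(range `s_z`), non-decision time ~
Uniform(range `s_t`). The likelihood uses the standard small-time /
large-time series for the first-passage density, closed-form integration of
Gaussian drift variability, and Gauss-Legendre quadrature for the uniform
variabilities; per-subject fits are penalized maximum likelihood over the
nine parameters (see `docs/methods.md`). Reading skill is then modelled as

    reading ~ v_comp + d_comp + a + PA + RAN + IQ (+ ADHD + age)

with all-subsets AIC selection, where `v_comp` (PC1 of the four drifts and
`s_v`) indexes sensory evidence quality and `d_comp` (PC1 of `s_t`, `t_nd`,
`s_z`) indexes decision variability. A nested F-test against the
phonology-only model `reading ~ PA + RAN + IQ` asks whether the DDM block
explains variance beyond phonology — the additive-vs-cascade question.

## Worked example

The numbered drivers under `analysis/` run the whole project and print
their findings; each writes tables under `results/`.

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_study1_classification.py
python analysis/03_preprocess_and_fit_ddm.py     # ~10 min for 106 subjects
python analysis/04_study2_models.py
python analysis/05_factor_analysis.py
```

Step 02 prints, for the synthetic clinic cohort (groups planted ~0.9 /
~0.8 SD apart on PA / RAN):

```
QDA LOO accuracy 64.2% (+/- 6.4%), sensitivity 68.2%, specificity 60.0%
  pa: d=0.90, dis-attenuated d=0.97
  ran: d=0.67, dis-attenuated d=0.72
```

i.e. phonological measures separate the groups far better than chance yet
misclassify roughly a third of individuals — the quantitative motivation
for hunting additional risk factors. Step 03 screens the simulated sessions
(RT window 200 ms-10 s; exclusion of incomplete, at-chance, and
over-window subjects; the 100% coherence condition dropped, leaving 240
analysis trials each) and fits the DDM per subject. Step 04 then finds the
planted additive structure on the fitted parameters:

```
additive model selected terms: ['v_comp', 'd_comp', 'a', 'ctopp_pa', 'ctopp_ran', 'nonverbal_iq']
DDM block F(3, 99) = 21.56, p = 7.932e-11; AIC selected 215.0 vs reduced 262.3
mediation: indirect -0.029 CI (-0.121, 0.036), direct 0.150 CI (0.004, 0.312)
```

— the DDM composites survive selection alongside phonology, the nested
F-test rejects the phonology-only model, and mediation by PA is at most
partial (the direct path's CI excludes zero; the indirect path's includes
it). Ward clustering of the fitted-parameter correlations separates the
drift block from the `t_nd`/`s_t` block and from `a` (the weakly identified
`s_z`/`s_v` estimates can migrate between clusters at this trial count).
Step 05 prints:

```
eigenvalues > 1: 5; parallel analysis retains 4
4-factor varimax solution explains 53.2% of total variance (17.2%, 16.7%, 10.6%, 8.7%)
unexplained variance in a: 96%
LOO-CV reading prediction: 4-factor R2 = 40.4%, single-factor (factor1) R2 = 20.4%
```

so the four planted dimensions are recovered, the boundary-separation
parameter stays essentially unexplained (it loads on no factor by
construction), and held-out prediction of reading skill from all four
factors roughly doubles the best single factor.

The same machinery is scriptable through a CLI
(`readrisk simulate-cohort | preprocess | fit-ddm | study1 | study2 | efa |
run-all`) for use on external trial/score CSVs; schemas are documented in
`readrisk/io.py`.

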