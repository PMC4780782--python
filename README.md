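# votcp

Categorical perception (CP) of voice onset time in developmental dyslexia:
a reusable pipeline for scoring phoneme identification/discrimination
experiments, subtyping dyslexic cohorts by phoneme-awareness (PA) and
visual-attention-span (VAS) deficits, and testing whether the CP→reading
link is mediated by phoneme awareness.

## Who this is for

Researchers analysing child psychophysics along a /d/–/t/ VOT continuum
(−75…+75 ms in 30 ms steps) together with cognitive batteries (phoneme
deletion/segmentation/acronyms, global/partial letter report, word and
pseudo-word reading). The package scores trial-level data, and it ships a
synthetic-cohort generator whose planted structure — dissociated PA and VAS
deficits and a CP→PA→reading path — lets every stage be exercised and
validated end to end without access to child data.

## The statistics at the core

**Boundary and predicted discrimination.** Identification responses give a
labeling curve p(VOT); the phonemic boundary μ is the 50% crossing of a
constrained maximum-likelihood logistic fit p = logistic((VOT − μ)/s).
Under covert labeling, the predicted probability that an AX pair (i, j) is
judged "different" is

    H = p_i(1 − p_j) + p_j(1 − p_i),   F = ½[2p_i(1 − p_i) + 2p_j(1 − p_j)]

and both observed and predicted scores become d′ = z(H*) − z(F*) with the
log-linear rate correction applied always. The discrimination peak (largest
d′; amplitude and center) indexes boundary precision.

**Group inference.** Split-plot ANOVA with Group between subjects and
Task (observed vs predicted) × VOT pair center (−30, 0, +30 ms) within,
Greenhouse–Geisser corrected, partial η² effect sizes; ANCOVA of peak
amplitude on Group with peak location as covariate; age-partialled
correlations among CP, PA, VAS and reading composites.

**Mediation.** Causal steps over three OLS models (standardized):
PA ~ age + CP; reading ~ age + CP + VAS; reading ~ age + CP + PA + VAS;
Sobel test z = ab/√(b²se_a² + a²se_b²) with a one-sided p.

## Worked example

```
votcp run --out demo --seed 1
```

simulates the default study (63 controls, 63 dyslexics split 17/20/7/19
into PA-deficit / VAS-deficit / double / no-deficit), scores all 126
children (60 identification + 80 discrimination trials each), and writes
`participants.csv`, trial tables, `cp_derived.csv`, `zprofiles.csv`,
`subgroups.csv`, `anova_results.csv`, `correlations.csv`, `mediation.json`
and `run.log` into `demo/`. At seed 1 the run prints/records, among others:

- group means of predicted peak amplitude: controls 1.31, dyslexics 1.08 —
  the planted lower boundary precision of the PA-impaired children shows up
  as a flatter predicted discrimination peak;
- mixed ANOVA: VOT effect F(2,248) = 110.7, ε_GG = 0.83, p < .001;
  VOT × Group F(2,248) = 4.66, p = .015 (the group difference concentrates
  at particular pair centers);
- age-partialled correlations (dyslexics only): predicted peak × PA = .34
  and PA × reading accuracy = .47, while predicted peak × VAS = −.17 and
  PA × VAS = −.18 stay small; VAS × reading speed = −.40;
- mediation paths a = .34, b = .47, c = .37, c′ = .22, d = .38; Sobel
  z = 2.36, one-sided p = .009. At this seed the direct path c′ remains
  significant, so the strict causal-steps verdict is "partial mediation" —
  `mediation.json` records each step flag separately.

`votcp simulate`, `votcp score` and `votcp analyze` run the stages
separately; `score` accepts externally collected trial files with the same
column contracts (see `docs/methods.md` and the module docstrings).

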