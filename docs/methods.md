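# Methods

`votcp` implements an end-to-end analysis of categorical perception (CP) of
voice onset time (VOT) in developmental dyslexia: stimulus-design
construction, cohort simulation, signal-detection scoring of identification
and discrimination data, deficit subtyping, group inference, and a
causal-steps mediation analysis linking CP to reading through phoneme
awareness (PA). This note records the models, the defaults and why, the
numerical choices, and what the synthetic cohort does and does not show.

## Experimental designs

The stimulus grid is a six-step /d/–/t/ VOT continuum, −75 to +75 ms in
30 ms steps. The identification block presents each level 10 times
(60 trials). The AX discrimination block presents the six identical pairs
and both orders of the five adjacent (one-step) pairs, five times each
(30 + 50 = 80 trials). Letter-report sets for the visual-attention-span
(VAS) tasks use 10 consonants (B P T F L M D S R H): global report is 20
five-letter strings with every letter used 10 times and exactly twice per
position; partial report is 50 strings with every letter 25 times, 5 per
position, and each (letter, position) combination cued exactly once. No
string repeats a letter, and adjacent letters never form a digraph or
frequent French bigram (default blocklist PH, TH, TR, PL, BR and reverses;
a full lexicon screen would need a word list, so the blocklist is the
configurable stand-in). The single-letter control presents each letter once
at each of five durations (33–101 ms, 50 trials).

Letter-report sets are built by dealing each column a balanced multiset of
letters (partial-report cue cells are pinned first), then repairing row
violations by within-column swaps, which preserve all column counts; a swap
is kept only if it strictly lowers the combined violation count of the two
touched rows, with seeded restarts. All builders are pure functions of
(parameters, seed): the multiset of conditions is fixed, only the order is
a Fisher–Yates permutation of a seeded generator.

## Response models in the simulator

Identification responses are Bernoulli draws from a logistic psychometric
function, P(/t/ | VOT) = logistic((VOT − μ)/s), with a participant-specific
boundary μ (ms) and slope scale s (ms; smaller = sharper). A logistic rather
than probit link is conventional for psychometric functions and nothing in
the analysis depends on the difference at these slopes.

Same–different responses follow yes–no signal detection on a true
discriminability

d_true(i, j) = d_max·|p_i − p_j| + w_allo·[exp(−(c+30)²/2w²) + exp(−(c−30)²/2w²)],

where p are the labeling probabilities, c the pair center, and the two
Gaussian bumps (width w = 10 ms) sit at the universal allophonic boundaries
±30 ms. Identical pairs have d_true = 0. The response is "different" with
probability Φ(d_true/√2 − c_resp), a single-criterion model whose scored d′
tracks d_true monotonically (verified by simulation). Defaults: d_max = 3.5,
c_resp = 0.5 (children answer "same" at chance-level evidence more often
than "different"), w_allo = 0 (school-age children show little behavioral
allophonic sensitivity; the term is there to generate allophonic perceivers
when wanted).

## Latent cohort structure

Each child carries standardized latent traits. CP sharpness is
−(s − mean_s)/sd_s. The planted path model mirrors the mediation hypothesis:

- pa_ability = a·cp + noise (a = 0.4)
- reading_acc = b·pa + c′·cp + d·vas + noise (b = 0.4, c′ = 0, d = 0.35)
- reading_speed = d·vas + noise (speed loads on VAS, not PA)

Four dyslexic classes with the subgroup sizes of the emulated study design
(17 PA-deficit, 20 VAS-deficit, 7 double-deficit, 19 no-deficit, plus 63
controls): PA-deficit children get a worse slope scale (+4 ms) and a −2 SD
shift on pa_ability with VAS untouched; VAS-deficit children the converse
(−2 SD on vas_ability, slope untouched); double-deficit children get both.
The −2 SD shift magnitude matches the subgroup mean Z-scores such cohorts
show on their impaired tasks. The explicit shifts are needed because the
deficits must dissociate: no structural path feeds vas_ability, so a
VAS-deficit class cannot arise from the path model alone. The double-deficit
class matters statistically: with only disjoint single-deficit classes, the
pooled dyslexic sample would show a spuriously negative PA × VAS
correlation; the double-deficit children offset most of it, keeping the
pooled association near zero, as dissociation studies report.

All dyslexics get a common −2.5 SD reading shift (accuracy and speed).
Boundary μ ~ N(5, 11²) ms — positively displaced from 0 ms, as French
voicing boundaries are — and slope s ~ N(8, 3²) ms truncated at 0.5 ms.

Task scores are clipped affine transforms of the latent traits,
score = norm_mean + norm_sd·(latent + task noise), with task noise SD 0.5.
The default norm table is a set of plausibility anchors on each task's
printed scale (e.g. phoneme deletion 83.4 ± 15.3 %, global report
83 ± 11 %, word reading 19 ± 1.5 /20), chosen once to sit in the range
typical of ten-year-old readers; every entry is configurable. Reading times
invert the speed latent (faster child → smaller time). Single-letter
control scores are at ceiling for everyone (the simulator does not model
low-level letter-identification failure).

What the generator does not emulate: item-level content of the PA tasks,
age-dependent norms (one norm stratum per cohort), floor/ceiling response
styles, lapses and attention drift in psychophysics, and any direct
VAS→PA coupling. Passing tests on this cohort therefore show that the
pipeline recovers the planted structure under idealized response models,
not that real child data would behave this way.

## Scoring

The identification curve is tallied per level; the boundary is a
constrained maximum-likelihood logistic fit on the binomial counts. The
slope scale is bounded below by one sixth of the grid spacing (5 ms on the
30 ms grid): with only six levels the unconstrained likelihood prefers
near-step interpolants of the raw proportions (s ≈ 1 ms), which biases the
crossing; slopes below the floor are not identifiable anyway because no
stimuli fall between levels. Degenerate curves (all one label) return a
missing boundary with `converged=False` and are dropped pairwise from
boundary correlations. Perfectly separated step data are fitted at the
midpoint of the separating gap, the constrained maximum by symmetry.
Per-curve precision is limited by design information: at s = 8 ms the
Cramér–Rao bound for μ is ≈5 ms per 60-trial block, so individual
boundaries carry substantial noise regardless of estimator.

Observed discrimination rates per adjacent pair: hits pool "different"
responses over both presentation orders; false alarms average the
"different" proportions of the two flanking identical pairs (both stimuli
contribute symmetric noise). Predicted discrimination converts the
identification curve through covert labeling — respond "different" iff the
two stimuli receive different covert labels — giving
H = p_i(1−p_j) + p_j(1−p_i) and F = mean(2p_i(1−p_i), 2p_j(1−p_j)).

d′ = z(H*) − z(F*) with the log-linear correction (add 0.5 to the count, 1
to the denominator) applied always, to observed and predicted rates alike,
so both share one transform and ceiling rates stay finite. Predicted rates
use the design's trial counts as pseudo-counts (10 and 10 by default). A
yes–no d′ is used rather than a differencing-model same–different d′ — the
simplest mapping consistent with treating the scores as plain d′ values;
under a differencing model the absolute values would shrink but the group
contrasts and correlations, which are what the pipeline tests, would be
preserved in order.

The discrimination peak is the pair with the largest d′; ties break toward
the smallest |center|, then toward the negative center (deterministic, and
biased toward the phonemic rather than allophonic region on full ties).
Boundary-distribution summaries report mean, sample SD, and bias-adjusted
Fisher–Pearson skewness (G1).

## Cognitive scoring and subgrouping

Z-scores are (value − reference mean)/reference SD. PA-task references come
from the cohort's own control group; reading and report tasks use the norm
table. Composites: PA = mean percent of the three PA tasks; VAS = mean of
the global and partial report percentages; reading accuracy = mean percent
of the three /20 accuracy scores; reading speed = mean of the three
time Z-scores with larger = slower (so speed correlates negatively with
reading skill). Children missing the 10/10 ceiling at any single-letter
duration are flagged for exclusion.

A dyslexic child is PA-impaired iff any PA-task Z < −1.5 (strict), and
VAS-impaired iff any report-task Z < −1.5; the 2×2 gives labels PA_only /
VAS_only / double / none. Age matching removes controls one at a time,
always the youngest (ties by identifier), re-testing the age difference by
one-way ANOVA until p ≥ 0.10 (the stop α is configurable; 0.10 is
conservative enough that matched groups are comfortably similar). The floor
defaults to twice the dyslexic group size; hitting it raises an error with
group means in the message.

## Group inference

The mixed (split-plot) ANOVA takes Group between subjects and Task
(observed vs predicted) × VOT pair center (−30, 0, +30 ms) within. Sums of
squares are computed through orthonormal within-subject contrasts; for each
within effect the contrast scores are analysed as a one-way between-groups
model. With unequal group sizes the within main effects use unweighted
group means (the Type III convention of mainstream ANOVA software); group
effects and interactions are unambiguous for a single between factor.
Greenhouse–Geisser ε comes from the pooled within-group covariance of the
cell scores, ε = tr(CSC′)²/(q·tr((CSC′)²)), clamped to [1/q, 1], and is
applied to every within effect with more than one degree of freedom,
regardless of a sphericity pretest. Effect sizes are partial η² =
SS_effect/(SS_effect + SS_error). Constant responses yield NaN F values
rather than errors.

The peak ANCOVA fits amplitude ~ Group + location + Group×location by OLS
and reports Type II F tests. Partial correlations residualize both
variables on age and use a t test with n − 3 df, two-sided; missing
boundaries are handled by pairwise deletion.

## Mediation

Three OLS models on standardized variables (so paths are standardized
coefficients): (1) PA ~ age + CP index, (2) reading ~ age + CP + VAS,
(3) reading ~ age + CP + PA + VAS. The causal-steps verdict requires a, c,
b significant at two-sided α = .05 and c′ non-significant. The Sobel
statistic is z = ab/√(b²se_a² + a²se_b²) with a one-sided upper-tail
p-value — the direction of the hypothesized positive indirect effect
(z = 1.40 ↦ p = .081). Because model 1 omits VAS, the exact decomposition
c = c′ + ab does not hold by construction; `mediator_model_includes_vas=True`
adds VAS to model 1, restoring the identity (used as a numerical check).
The exploratory choice of CP index is exposed as `select_cp_index`, an
age-partialled scan over candidate indices that logs every candidate's r
and p rather than silently picking one.

## Numerical and testing choices

Seeds derive from a root `numpy` SeedSequence; identical configs give
byte-identical outputs. Optimization uses L-BFGS-B on (μ, log s) with three
starts. The acceptance checks run the default study at n = 63 + 63 over 20
seeds (~2 minutes) and recovery simulations at 200–1000 replicates on
latent traits — sizes chosen to keep the whole suite a few minutes while
leaving the binomial/sampling noise small relative to the asserted margins.

Known limitations: per-child boundary estimates are noisy at the design's
information limit (above); the qualitative association pattern is a
sampling-variable property at n = 63, so a minority of seeds can miss single
checks; the ANOVA assumes a complete within design (no cell imputation);
and the simulator's clipping can compress task-score variance for extreme
latent values, slightly attenuating correlations near floor or ceiling.
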