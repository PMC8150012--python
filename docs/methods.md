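# Methods

This note documents the models, parameter choices and numerical
decisions behind `foodict`. It describes what the package computes; every
number quoted as output is produced by the test suite or the analysis
scripts, not asserted by hand.

## Generative model of the synthetic cohort

The generator reproduces the statistical structure a two-arm food
GNG/CAT trial assumes at the design stage, not the idiosyncrasies of any
real cohort.

**Ratings.** For participant *i* with subject offset `b_i ~ N(0, σ_b)`
(σ_b = 15 points on the 0–100 analogue scale) and item *j* with base
palatability around the low 60s, the pre-intervention rating is
`clip(base_j + b_i + jitter_ij, 0, 100)` with item jitter SD 5. The
pre→post change is drawn **once per participant × category cell**:
`Δ_{g,c} + ε_ic`, `ε ~ N(0, σ_c)` with σ_c = 7; per-item post ratings add
this cell change to the item's pre rating. The 7 and 15 are read as
standard deviations (of the change and of the subject offset), not
variances: this is the only reading under which the printed design-stage
sample sizes (23 and 43 per group) are reproduced by the simulation; a
variance reading misses them by a wide margin. Cell-level change draws
match the design-stage model exactly, while item-level jitter gives the
selection/trimming pipeline realistic input.

**Weights.** Each of the four timepoints (pre, post, 1-month, 4-month)
is `baseline_i + Δ_{g,t} + ε`, `ε ~ N(0, 1 kg)`, with the baseline taken
from the participant profile (BMI × height²; between-subject SD ≈ 10 kg).
The default experimental profile is (0, −1, −1, −1) kg: a 1 kg loss
reached by post-intervention and maintained — consistent with a healthy
loss ceiling of ≈0.45 kg/week over one month. The time profile of the
effect is a genuinely open design choice; "lose 1 kg and keep it" is the
most conservative profile consistent with the stated smallest effect.
Missingness is independent per timepoint; the default 4-month rate is
1/3, the rate such trials observe at long follow-up.

**Defaults are study conditions.** Planted effects default to the
smallest effects of interest (−5/+5 rating points in the experimental
arm, −1 kg), expectancy rates to 77% (control) / 95% (experimental) for
expected valuation, and the eligibility fields to values that pass the
screen; `ineligible_fraction` plants violations for testing the screen
itself. One seed drives everything, split per table in a fixed order
(cohort, items, ratings, weights, expectancy, geq), so any single table
can be regenerated without the others.

**What the generator does not model:** real food-image properties,
learning curves beyond the agents' fixed parameters, informative
dropout, or any coupling between the valuation mediator and weight
beyond their common dependence on the arm. Passing tests therefore
demonstrate that the pipeline recovers what it assumes — parameter
recovery and calibration — not that the substantive effects exist in
real populations.

## Power analysis

Per hypothesis: simulate the design at each candidate per-group n
(default grid 20…60 by 10), fit the mixed ANOVA, record the fraction of
interaction p-values below α = 0.05, and take the smallest n reaching
0.9 power. Because the crossings fall off-grid, an integer bisection
stage refines between the bracketing grid points at the full replicate
count. Each evaluated n uses an RNG seeded from (seed, n), which makes
the minimal n invariant to the starting grid (asserted in tests).

The interaction tests are computed with closed-form equivalents of the
mixed-ANOVA F, vectorized across replicates: squared pooled two-sample
t on change scores (2×2), on difference-of-difference scores (2×2×2),
and the full repeated-measures interaction F from its sums of squares
(2×4). Each equivalence to the `stats_analysis` engine is asserted to
1e-8 in the suite. The default replicate count is 2 000 (Monte Carlo SE
≈ 0.007 at power 0.9), a desk-scale choice; the SE is reported with
every estimate so the precision is explicit.

With these conditions the 0.9-power crossings land at 21–23 (triple
interaction) and 42–43 (single food type) per group. The weight design
is the one place where the full 2×4 interaction disagrees with the
published design stage: the 3-df interaction with offsets (0,−1,−1,−1)
and σ = 1 kg has noncentrality 0.375·n per group, so 0.9 power needs
≈38 per group, whereas a pre/post change-score contrast with d = 1
needs 22. The package implements the stated 2×4 interaction and reports
its own crossing (~37–39); the discrepancy is documented rather than
papered over, and the pre/post contrast is available through the same
API (`PowerSpec("S2x2", 10, 1, ...)`) for comparison.

The mediation sample size is the closed form
`n = (z_{1−α/2}+z_{power})² σ_e² / (b₂² σ_m² (1−ρ²))`, ceiled; with the
default parameters (b₂ = 0.1, σ_m = 7, σ_e = 1, ρ = 0.3) the raw value
is 23.57 → 24.

## Task engine

Difficulty is an 18-level table of shrinking response windows (GNG:
the reaction-time threshold, 1.1 → 0.33 s; CAT: the response window
after cue onset, 0.88 → 0.25 s). The CAT row is interpreted as the
window itself (stimulus duration minus go-signal delay): a shrinking
window is the only reading under which a higher level is harder.
Promotion needs consecutive successes — six for GNG (hits and correct
rejections both count), three for CAT (cued hits only); any
miss/false-alarm/too-late resets the streak; a CAT correct rejection
neither counts nor resets. Consecutive counting is the standard
staircase convention; no demotion occurs on errors (only the purchasable
difficulty-decrease power-up lowers the level).

Gauges: "too late" drains the speed gauge, miss/false-alarm the accuracy
gauge; both start at 5 and an empty gauge ends the run, after which a
fresh run starts at level 1. Points: 10 × level per hit; a CAT correct
rejection awards ⌊hit/3⌋ — the exact amounts are a game-design free
parameter, but the 1:3 CAT ratio is fixed and asserted. Power-ups for
one task are payable only with the other task's currency. Go-category
(sweet vs salty) alternation across sessions is deterministic by session
index.

Responder agents draw lognormal reaction times and lapse/commit with
fixed probabilities; they are deliberately stationary (no learning),
since the engine, not the agent, is the object under test.

## Exclusion pipeline

Eligibility: age 18–45, BMI > 20 (strict), ≤ 2 Likert points between
sweet and salty liking, and six disqualifying flags. Adherence over the
20 training days: drop if > 2 days untrained, > 5 days under 20 minutes,
or ≥ 7 days that never exceeded difficulty level 5 in either task ("more
than a third" is implemented as the stated 7-day count; an untrained day
trivially fails the level rule too).

Palatability: participants with an incomplete pre or post questionnaire
are excluded; responses faster than 300 ms are dropped (300 ms itself is
kept — the rule is strict "shorter than"); training uses the items
strictly above each subcategory's pre median (ties at the median break
by ascending item id; an all-tied subcategory falls back to the top
half); the analysis score is the mean over trained items after trimming
⌊0.2·m⌋ items at each end of the pre distribution, per category — the
trimming operates on the trained set, since only trained items re-enter
the post questionnaire. MAD screening (k = 2.5, scale 1.4826; the
consistency constant is a config switch) is applied to the healthy and
unhealthy participant-mean distributions; a zero MAD flags everything
off the median with a warning.

Weights: guideline-violating records are dropped (the violation is a
recorded boolean, not inferred); the participant-mean weight
distribution is screened at 2.5 MAD. If more than 20% of participants
(strict) miss any weight point, the joint 2×4 design is replaced by
three independent contrasts (pre/post, pre/1M, pre/4M), under which a
3-MAD delta outlier only loses the offending later data point; under the
joint design delta outliers and any-missing participants are removed
entirely.

## Confirmatory statistics

The ANOVA engine computes the classical multistratum decomposition for
complete repeated-measures data with one between factor and one or two
within factors. Group sizes may differ; the within strata remain
proportional, so sequential and Type-III sums of squares coincide for
all interaction terms (the tested terms). Partial η² is
SS_effect/(SS_effect + SS_error); generalized η² divides by SS_effect
plus all subject-related SS. The engine is validated against an
independent implementation (pingouin, exact agreement on the 2-way
case) and against the t² identities.

Bayes factors in favour of the null use the BIC approximation
`BF01 = exp((BIC_alt − BIC_null)/2)` on the change-score model
comparison (intercept-only vs group), generalized to multi-level within
factors via stacked orthonormal contrast scores. This differs from
default-prior JZS Bayes factors by construction; reports label the
method, and no JZS value is treated as a reference.

Mediation is the linear two-equation system (M ~ X; Y ~ X + M); ACME =
a·b, ADE = c′, with percentile bootstrap CIs over 1 000 participant
resamples. It is gated: it runs only when a weight interaction is
significant with the experimental arm losing more, and refuses (with
the reason recorded) otherwise. Distribution screening reports sample
skewness and excess kurtosis against configurable thresholds (defaults
2 and 7 — the trial states thresholds exist but not their values); the
nonparametric mixed-model fallback is a stub, as the contingency it
covers never triggers on data that pass the screening.

The expectation-share decomposition divides the control arm's excess
unhealthy devaluation by its total unhealthy devaluation,
`round(100·(ΔU − ΔH)/ΔU)`: the control group expected healthy items to
gain value, so its healthy-item devaluation bounds the
non-expectation component.

## Quality controls

Baseline balance uses Cohen's d (df-pooled SD) with a 0.3 criterion;
the gender ratio uses a standardized proportion difference.
Game-experience scoring reverses tension/annoyance and negative affect
item-wise (4 − raw), keeping every component score bounded; the global
index is the six-component sum. Imbalance is repaired by iteratively
removing the participant farthest from the pooled median (game
experience) or closest to the scale midpoint (items liking).

Expectancy blinding is measured by φ on the 2×2 group × expectancy
table; while |φ| > 0.2 the cell with the largest observed-minus-expected
count (ties to the smallest cell index, with a 1e-9 tolerance so
floating-point noise cannot override the tie-break) loses one uniformly
random participant — or has one redrawn at the configured base rate in
replace mode, which is capped at 10·n steps since redraws are
stochastic. The χ² test is computed without continuity correction (so
χ² = n·φ², asserted), switching to Fisher's exact test when any cell is
below 5; it is reported descriptively only.

## Problem sizes and tolerances

Simulation-heavy checks run at 2 000 replicates (null calibration bands
are α ± 3·MC-SE), parameter recovery at 200 participants per group over
100 replications, scheduler checks at 10⁵ trials, and the oracle
comparison for MAD screening at 1 000 random vectors. Numerical
identities (F = t², φ identities, ACME additivity) are asserted at
relative 1e-8.

## Known limitations

- The weight-design power discrepancy described above: the 2×4
  interaction crossing (~38/group) is reported as computed and does not
  match the 22 a pre/post contrast yields.
- BIC Bayes factors are not comparable in magnitude to default-prior
  JZS values.
- Agents do not learn within or across sessions, so simulated training
  logs understate the level progression of real participants late in
  training.
- The generator's independence assumptions (ratings ⊥ weights given
  arm) make the mediation ACME truly zero on synthetic data; the
  mediation machinery is validated by direct parameter recovery on
  constructed (X, M, Y) triples instead.
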