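# Methods

## The model

`moraltides.model` implements a cultural-evolution account of moral norm
change in a well-mixed population of two moral types. A proportion *q* of
agents are moral liberals, with whom only *individualizing* arguments
(harm, fairness, liberty) resonate; the remaining 1 − *q* are moral
conservatives, with whom individualizing and *binding* arguments
(authority, loyalty, purity) resonate equally. On each issue, one of the
two opinions is better supported by individualizing arguments; the size of
this *argument advantage* is *a* ∈ (0, 1]. Each time step an agent is with
probability *d* exposed to a uniformly random other agent's opinion; on
hearing a different opinion, conservatives switch with probability *s* in
either direction, while liberals switch with probability *s* toward the
advantaged opinion but only (1 − *a*)*s* away from it.

With *l*ₜ and *c*ₜ the popularity of the advantaged opinion among liberals
and conservatives, the mean-field (infinite-population) recursion is

    l_{t+1} − l_t = d·s·[ a(1 − l_t) p_t − (1 − a)(1 − q)(l_t − c_t) ]
    c_{t+1} − c_t = d·s·q·(l_t − c_t),        p_t = q·l_t + (1 − q)·c_t.

Both updates use time-*t* values on the right-hand side (synchronous map).
Consensus states (0, 0) and (1, 1) are exact fixed points. From a symmetric
start with *a* > 0, liberals stay weakly ahead of conservatives and overall
popularity is non-decreasing, converging to full adoption; accumulated
change over a fixed horizon is non-decreasing in both |*a*| and *q*. These
laws are enforced by the test suite rather than assumed.

The interface accepts a *signed* advantage: a negative *a* means the
*opposite* (negatively coded) opinion is advantaged. The dynamics always
run with |*a*|; `accumulated_change_profile` negates the reported change
for negative signs, which makes profile statistics exactly antisymmetric
under recoding and matches how signed advantage scores are tabulated.

The agent-based twin (`simulate_agents`) applies the same micro-rules to a
finite population with `floor(q·n)` liberals. Initial opinions are i.i.d.
Bernoulli draws by type (deterministic rounding available via a flag, since
finite-population initialization is underdetermined by the mean-field
description). Partners are drawn uniformly among the *other* n − 1 agents
and updates are synchronous on the time-*t* opinion vector. Replicate means
at n = 10⁵ agree with the mean-field trajectory within three Monte-Carlo
standard errors at every recorded step; the comparison records every 20th
step, where adjacent deviations are strongly autocorrelated.

Numerical choices: state variables are clamped into [0, 1] only when
floating error drives them out by at most 1e−12; larger excursions raise,
so clamping can never mask a logic bug. Fig-style defaults *d* = 0.1,
*s* = 0.5 are conventional plumbing values — only the products *d·s·t*
matter for the deterministic dynamics, so they set the time scale, not the
substance.

## Argument-advantage scoring

A rater states a dichotomous position on an issue and rates the
applicability of one argument of each of seven kinds (Harm, Violence,
Fairness, Liberty, Authority, Loyalty, Purity) to their own and to the
opposite position, on a five-point scale coded 0, 0.25, 0.5, 0.75, 1. The
participant score for the positively coded opinion is mean(own kinds) −
mean(opposite kinds) over a kind-set, orientation-flipped for raters
holding the negatively coded opinion; the issue score is the unweighted
mean over raters, pooling societies by default. Kind-sets: `standard` =
{Harm, Fairness, Liberty}; `prereg` additionally includes Violence (a harm
sub-kind); `binding` = {Authority, Loyalty, Purity}. Raters failing a
10-item vocabulary screen (fewer than six correct) are excluded before
scoring. A "some other reason" survey option, where present, enters no
formula and is ignored. Missing applicability cells are errors, not
imputed: the survey design forces complete 14-cell grids.

Cross-group agreement of issue profiles uses Lin's concordance correlation
coefficient, CCC = 2·cov(x,y) / (var(x) + var(y) + (mean x − mean y)²),
with population (n-denominator) moments and no small-sample bias
correction — the plain textbook definition. Its bootstrap CI resamples
issues (mirrored pairs travel together), percentile method.

## Moral liberalness (LIB)

LIB is a society's mean reliance on individualizing minus binding
foundations, computed from MFQ-style tables. Responses are linearly
rescaled so each study's scale spans [0, 1]; within a country-study cell,
standardized responses are averaged per item, item means per foundation
group, and LIB = mean(harm, fairness items) − mean(authority, loyalty,
purity items). With complete data, item-first and participant-first
averaging coincide; item-first is canonical here. Countries in several
studies get the unweighted average of per-study values ("average" is
taken literally; no sample-size weighting). A `liberty` foundation label
is accepted but enters neither side of the difference, which names only
harm/fairness vs authority/loyalty/purity. LIB serves as the observable
proxy for the model's *q*.

## Norm-change estimation

Graded survey responses are dichotomized by per-item scale specs
(for 10-step justifiability items: 7–10 → 1, 1–4 → 0, 5–6 excluded).
Change rates are slopes of weighted logistic regressions of agreement on
time in decades — log odds per 10 years. Individual rows are reduced to
weighted binomial aggregates per society-issue-wave, which preserves the
weighted likelihood; consequently estimates are invariant to rescaling all
weights (CIs are not, as information scales with total weight).

*Fixed-effects estimator* (per issue): binomial GLM of the agreement share
on decade time plus society dummies, Wald CIs. The two-wave one-society
case has the closed form logit(p₁) − logit(p₀), which the tests pin.
Near-separated designs are flagged, not raised.

*Multilevel estimator*: the target is a logistic model with random
intercepts by issue and society-issue and a random slope by issue; the
per-issue quantity of interest is the global slope plus the issue's slope
deviation. The realization is two-stage empirical Bayes: per-issue
fixed-effects slopes bⱼ with standard errors (society dummies playing the
society-issue intercepts), then a normal-normal hierarchy with the
DerSimonian–Laird moment estimate of the between-issue slope variance τ²
and posterior-mean shrinkage of each bⱼ toward the precision-weighted
global slope. The estimator contract is stated in recovery terms — mean
absolute error of per-issue rates below 0.05 on hierarchical synthetic
panels (20 issues × 20 societies × 3 waves, n = 500/wave), agreement with
the fixed-effects fit within 0.02 when slope heterogeneity is absent — and
the suite verifies both. This realization was chosen over a Laplace GLMM
fit because it is deterministic, fast, free of convergence failures on
unbalanced panels, and satisfies the contract with a wide margin; with
rich per-issue information it is asymptotically equivalent.

*Period splits*: society-items measured at least three times are split at
the observed wave closest to the calendar midpoint (first + last)/2, ties
resolved to the earlier wave, with the pivot wave in both halves.

*Interaction model*: the three-way moderation of change by per-issue
argument advantage (AA) and per-society liberalness (LIB) is estimated
with eight fixed effects {intercept, time, AA, LIB, AA×LIB, time×AA,
time×LIB, time×AA×LIB}; time is calibrated to zero at the first year an
issue was measured in *any* society, in decades. Realization, under the
same contract: stage one fits a two-parameter weighted logistic
(level, slope) to each society-issue cell, with a Haldane 0.5 pseudo-count
guard at boundary shares; stage two regresses cell slopes and cell levels
on AA, LIB and AA×LIB with linear mixed models grouped by issue (random
intercept and random LIB coefficient per issue). The slope regression
supplies the four time-interaction coefficients and the "time by issue" /
"time×LIB by issue" variance components; the level regression supplies the
four level coefficients, the issue-intercept and "LIB by issue" components,
and its residual SD estimates the society-issue intercept SD. Stage two is
unweighted across cells; with comparable cell sizes (the synthetic design)
this costs little efficiency. The contract checks: the time×AA×LIB sign is
recovered in ≥95% of replications under a positive generating effect, and
the estimate is unbiased (mean within 2 SE of zero across replications)
under the null.

## Profile statistics and prediction tests

Every profile statistic includes both opinions of each issue: per-issue
values v are mirrored into (v, −v) pairs, so results are exactly invariant
to the arbitrary positive coding and mirrored profiles have mean zero,
making Pearson's r equal the uncentered correlation Σxy/√(Σx²·Σy²) (the
suite checks this identity to 1e−12). Bootstrap resampling draws whole
issues — each draw carries a pair's two values into the resample — with
percentile CIs, default B = 10,000 (B and method are pinned here because
library defaults vary). Resamples with undefined statistics (zero
variance) are redrawn and counted.

The five prediction tests:

* **P1, cross-society consistency** — societies are repeatedly partitioned
  into two random halves (sizes differing by one when odd, since equal
  sizes are impossible); each group's profile is the unweighted per-issue
  mean over member societies with data (unweighted for symmetry with the
  LIB aggregation); issues present in both group profiles enter the
  mirrored correlation, others are dropped from that partition and logged.
  Default 300 partitions, seeded and fully reproducible.
* **P2, period consistency** — mirrored correlation between early- and
  late-period global change profiles over issues eligible for the period
  split.
* **P3, advantage–change correlation** — mirrored correlation between the
  argument-advantage profile and the global change profile, with
  issue-bootstrap CI; the binding-advantage variant is computed alongside
  (its expected sign is negative, since binding advantages mirror
  individualizing ones).
* **P4/P5, liberalness moderation** — the AA×LIB and time×AA×LIB
  coefficients of the interaction model, with signs, CIs and p-values.

`evaluate_predictions` assembles whatever ingredients exist into a
JSON-serializable report; missing ingredients yield explicit
"not computed" blocks rather than silent gaps.

A note on the P1 null check: the correlations from different partitions of
the *same* dataset are dependent (they reuse the same societies), so a
dataset-level component survives averaging over partitions and SD/√(number
of partitions) is not a valid standard error for their mean. Unbiasedness
under a no-shared-profile null is therefore assessed across independent
synthetic datasets, not within one.

## Synthetic worlds

`moraltides.synthetic_data` generates complete ground-truth worlds:
societies with LIB ~ Uniform(0.05, 0.35) (the span observed in
cross-cultural foundation studies), mapped to the model's q by the
monotone link q = clip(LIB + 0.3, 0.05, 0.95) — any strictly increasing
link is admissible since LIB is a proxy for q; issues with a shared signed
advantage ~ Uniform(−0.6, 0.6) (the span of measured advantage scores),
identical across societies by assumption; and latent popularity per
society-issue from the mean-field model, run from a symmetric 50/50 start,
optionally with a burn-in period before the first survey wave so that
norms at first measurement already reflect accumulated change (further
along in more liberal societies — the P4 pattern).

Observable layers: opinion panels draw binomial agree counts
(default 3 waves over 20 years, n = 2000/wave, unit weights) around the
latent popularity, with optional society-item missingness; applicability
ratings place the issue's advantage symmetrically on the individualizing
cells (±a/2 around a base applicability of 0.5, binding cells mirrored
with the opposite sign), add Gaussian rater noise, and discretize onto the
five-point grid by *stochastic rounding*, which adds variance but no bias,
so scored advantages are centred on the truth; MFQ responses encode each
society's LIB as the individualizing-minus-binding gap in standardized
latent means, emitted in 6-, 7- and 5-point study formats with the same
unbiased discretization.

What the generator does not emulate: questionnaire wording and item
idiosyncrasies, interviewer and mode effects, realistic survey-weight
construction, correlated item non-response, society-level confounds
(economic change, cohort replacement), or time-varying argument
advantages. Passing recovery tests therefore shows that the estimators
recover the truth *when the model's assumptions hold*, not that real
survey archives satisfy those assumptions.

## Problem sizes and reproducibility

Simulation-based checks use sizes chosen to make each check informative at
interactive runtimes: agent-based/mean-field agreement at 10⁵ agents, 200
steps, 20 replicates; hierarchical-recovery panels of 20 issues × 20
societies × 3 waves at n = 500/wave; interaction sign recovery over 100
replications (50 under the null); bootstrap coverage measured over 600
simulation replications at B = 1000 (Monte-Carlo SD ≈ 1%); end-to-end
synthetic worlds of 15–20 issues × 16–20 societies at n = 1500–2000/wave,
sized so the three-way interaction CI excludes zero under the generating
effect. All randomness flows through seeded numpy Generators; identical
seeds give bit-identical trajectories, partitions and resamples.

## Known limitations

* The two-stage estimators are approximations to joint maximum likelihood;
  with very few waves per cell, few issues, or extreme shares their
  shrinkage targets and standard errors are rougher than a full GLMM's.
  The contract tests bound their error only under the simulated designs.
* Wald CIs are used throughout for change rates; profile-likelihood or
  bootstrap CIs for single-issue rates are not implemented.
* The packaged table of published values carries its source's printed
  precision (two decimals); statistics recomputed from it inherit that
  rounding.
* Real-data ingestion (survey-archive dialects, codebooks, press-freedom
  society filters) is out of scope; the society-inclusion list in the run
  configuration is the only filtering hook.
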