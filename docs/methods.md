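# Methods

This note documents the modelling assumptions, parameter conventions,
numerical choices and known limitations of `svoconform`. It states no
empirical result that the test suite does not itself compute.

## Task geometry

Alternative allocations live on the integer lattice within one point of the
circle of radius 50 centred at (50, 50) in (self, other) payoff space. The
selection rules — band distance in [49, 51] inclusive, polar angle within
±112.5° of the self axis inclusive, `pi_self ≤ 100`, `pi_other ≠ 50`,
`0 ≤ pi_other ≤ 100` — are applied in that order and yield exactly 406
alternatives, 203 prosocial and 203 antisocial. Inclusive band and angle
boundaries are the convention under which the enumeration reaches this
count; the test suite re-applies every predicate to the generated set.

The partition into four subsets (102/102/101/101) is not uniquely
determined by the published description beyond "evenly distributed around
the arc"; we sort by angle and deal round-robin, which is deterministic and
leaves every subset's mean angle within a fraction of a degree of the full
set's. The two 102-trial subsets serve the baseline condition's choice
phases, the two 101-trial subsets the other conditions', and the
manipulation phase draws 63 angle-stratified trials from a held-out subset.
The nine self-advantageous trials (`pi_self` ∈ (100, 110], `pi_other` = 50)
are synthetic stand-ins drawn uniformly without replacement: only "more
than 100 points for the self, 50 for the other" is specified for the
originals, which are deposited with the study materials and not
reproduced here.

Angles are computed in radians internally and exposed in degrees
everywhere, matching the field's reporting convention.

## Choice models

All six models share the linear value rule `V = pi_self +
tan(alpha)·pi_other` with the default's bias `V(D) = 100 + tan(alpha)·50 −
kappa`. Attitudes are constrained to (−90°, 90°), where tan is defined;
the task's allocations only span ±112.5° of *allocation* angle, but an
*attitude* outside ±90° has no meaning under the value rule.

* Stable family: `logit Pr(D) = (V_D − V_A)/tau`, `tau` in points.
  `tau → 0` recovers the deterministic value maximiser.
* Variable family: per-trial attitude draw from Normal(mu, sigma), sigma in
  degrees. The indifference threshold is
  `T_alpha = atan((pi_self − 100 + kappa)/(50 − pi_other))`; the probability
  of the default is the Gaussian mass on the default's side of `T_alpha`
  (probit link), with the side switching at `pi_other = 50`.
* Lapse: `Pr(D) = (1 − eps)·Pr_model + eps/2`, `eps ∈ [0, 1]` in data
  structures; during fitting its support is capped at 0.5 because a lapse
  above one half is indistinguishable from label flipping mixed with a
  smaller lapse.

**Degenerate trials** (`pi_other = 50`, the selfish alternatives) have a
value difference `V_A − V_D = pi_self − 100 + kappa` that is exactly
attitude-free. They contribute a softmax term under the stable family and a
hard step (0.5 at exact indifference) under the variable family, then are
lapse-mixed. This is the algebraic limit of each family's rule, not a
special-case convention.

Likelihoods floor each trial probability at 1e-300 before the log for
numeric safety on extreme parameter proposals. Missing responses never
enter likelihoods.

## Hierarchical estimation

Each subject-level parameter is sampled on a transformed scale — identity
for attitude and kappa, log for tau/sigma, logit of `eps/0.5` for the lapse
— and drawn from a group-level Normal whose location and scale carry weakly
informative hyperpriors:

| parameter | scale | location prior | scale prior |
| --- | --- | --- | --- |
| attitude | degrees | Normal(0, 30) | Half-Normal(20) |
| log variability | log deg / log pts | Normal(log 10, 1.5) | Half-Normal(1) |
| kappa | points | Normal(0, 10) | Half-Normal(10) |
| logit(eps/0.5) | — | Normal(−2.5, 1.5) | Half-Normal(1) |

These cover the parameter ranges the task can express (attitudes within the
arc, variabilities from a couple of degrees to tens of degrees, biases of
tens of points, lapses well below one half) without favouring any reported
value. The two task phases are treated as exchangeable draws from the same
group level; no before/after correlation parameter is estimated. Under the
shared-attitude (shared-variability) schemes the tied parameter is a single
subject-level quantity informed by both phases.

Sampling is Metropolis-within-Gibbs: element-wise Gaussian random walks
over subjects (vectorised, one proposal scale per parameter type and
phase), a conjugate Gibbs draw for each group location, and a log-scale
random walk for each group scale. Proposal steps adapt toward 44%
acceptance in windows of 50 iterations during burn-in only, so the
post-burn-in chain is a fixed-kernel Markov chain. Attitude proposals
outside ±89° are rejected (an implicit truncation of an already
vanishing prior tail). Chains are initialised from a moment heuristic (the
mean polar angle of each subject's chosen alternatives, clipped to ±60°)
plus per-chain jitter.

Defaults are desk-scale — 4 chains × 2000 iterations, 500 burn-in, no
thinning — with the published-scale settings (4 × 100 000, 5000 burn-in,
thinning 4) available via `MCMCConfig.paper_scale()`. Convergence is
summarised by split-R̂ and bulk ESS over all subject- and group-level
draws; any split-R̂ above 1.05 flags the fit unconverged with a warning,
never silently. Slow-mixing components are typically the weakly identified
lapse parameters and group scales; point estimates of attitude and
variability stabilise much earlier, which is what the recovery tests
measure.

**DIC** uses Spiegelhalter's form: `DIC = D̄ + p_D` with `p_D = D̄ −
D(θ̄)`, the plug-in deviance evaluated at the posterior means of the
subject-level parameters on their natural scales. This is the JAGS-era
default and the form most comparable to published DIC tables. **MAP**
estimates are per-parameter posterior modes: a Gaussian KDE with Silverman
bandwidth over the pooled marginal draws, maximised on a 512-point grid;
degenerate (zero-variance) draw sets return their common value.

## Synthetic participants

The generator reproduces the statistical structure the analysis assumes:

* 75/25 prosocial/antisocial attitude mixture, Normal(+20°, 14°) and
  Normal(−22°, 20°) respectively, truncated to ±85°;
* a 17% compliant subpopulation with kappa ~ Normal(11.48, 4) points versus
  Normal(1.14, 2) for the rest (means as reported for the two compliance
  groups; the spreads are our choice, wide enough to overlap but separate
  under recovery);
* sigma ~ LogNormal(log 10°, 0.4) before the manipulation, multiplied by
  LogNormal(log 0.85, 0.15) after — consistency rises in every condition;
* lapse ~ Uniform(0.01, 0.05) per phase;
* agents at ±45° whose sign matches the participant's raw-choice
  classification (the half-angle score; ties classify prosocial, logged as
  degenerate), simulated with sigma 2° and lapse 0.01 — "carefully
  calibrated" consistency so the agent is easy to predict. Group agents are
  five members' modal choices; the computer agent mimics the group;
* condition-dependent attitude shifts toward the agent of 0/4/6/5° for
  baseline/computer/individual/group (capped at the agent's position),
  applied to the compliant subgroup in the computer condition and to the
  non-compliant subgroup in the human conditions, plus Normal(0, 3°)
  jitter. This is the generative pattern the measures and statistics layers
  are designed to detect: no systematic convergence without an agent,
  demand-driven convergence toward a computer, genuinely social convergence
  toward humans;
* manipulation-phase predictions as Bernoulli hits at 93% accuracy
  (matching a late-block hit rate of 18.6/20), used descriptively only;
* 4-point Likert norm ratings from a latent appropriateness
  `sign(attitude)·(pi_other − 50)/50` plus Gaussian noise (SD 0.6), cut at
  (−0.5, 0, 0.5).

The after-phase attitude is a deterministic shift plus jitter, **not** a
learning process: the pipeline measures conformity, it does not model the
trial-by-trial dynamics that produce it. Reaction times, screen-side
randomisation and payment realisation are not simulated. Consequently,
passing tests demonstrate that the estimation and testing machinery
recovers the structure it assumes — they do not validate that structure
against real behaviour, and the norm-rating model in particular is a
stand-in with no quantitative empirical anchor.

All randomness flows from one master seed through per-participant
substreams keyed by (seed, condition, index), so populations are stable
under reordering or resizing of other conditions.

## Measures and statistics

The compliance index uses answered trials only in its denominators and is
undefined when a participant answered no prosocial or no antisocial trial;
such participants are excluded from compliance analyses (the measures table
carries a missing value). The 25% threshold is inclusive ("at least once
out of every four choices"). Attitude convergence penalises overshooting
past the agent by construction; the signed polarisation measure
`sgn(alpha_obs)·(alpha_after − alpha_before)` is the robustness companion.

The battery wraps established implementations where they exist: scipy for
the Wilcoxon signed-rank (exact null for n ≤ 25 without ties, else normal
approximation with continuity correction), Kruskal-Wallis H and Spearman's
rho; statsmodels RLM for Huber M-estimation (tuning constant 1.345, 95%
Gaussian efficiency). Dunn-type post-hoc z tests with tie-corrected pooled
rank variance are computed in-package, as is the Holm correction (used for
post-hoc families and across the norm-rating batteries). Effect sizes are
matched rank-biserial correlations, Glass rank-biserial for rank-sum
comparisons, and epsilon-squared `H/(N−1)` for Kruskal-Wallis, each with a
seeded 2000-replicate percentile-bootstrap 95% CI (the CI method behind
published bracketed intervals is unstated; bootstrap is our choice and its
coverage is property-tested). The Wilcoxon result also reports `log(V)`,
the natural log of the signed-rank statistic, mirroring the field's
reporting format.

JZS Bayes factors integrate the noncentral-t likelihood over a
Cauchy(0, r) effect-size prior via the substitution `delta = r·tan(u)`
(finite smooth integral, adaptive quadrature); directional variants
truncate and renormalise the prior on a half-line. The default scale is
√2/2; the norm-rating comparisons use the wide prior r = 2. The
implementation is cross-checked in tests against an independent fine-grid
trapezoid oracle and against pingouin.

The power routine returns the smallest n whose noncentral-t power meets the
target, by doubling bracket and bisection; it reproduces n = 90 for
d = 0.35, α = .05, power = .95 (one-sample, one-tailed). The floor is n = 2;
note that at power .95 even very large effects (d ≈ 5) still require n = 3
because the df = 1 noncentral-t has heavy tails — the floor is reached only
for d of a few tens.

## Problem sizes in the test suite

Closed-loop checks run at sizes chosen for a single CPU: parameter recovery
uses 60 subjects × 100 trials per phase with 4 × 2000 MCMC iterations;
model recovery uses ten replicates of 12 subjects × 80 trials per phase
with subject-phase parameters drawn i.i.d. from the group distributions
(the hierarchical model's own generative process) and 2 × 900 iterations
per fit; the direction-pattern experiment simulates 100 participants per
condition and evaluates measures on generator ground truth; calibration
suites use 2000 null replicates per test. These sizes are the package's
desk-scale defaults, not statements about the original study's scale.

## Known limitations

* Metropolis-within-Gibbs mixes slowly for weakly identified parameters
  (lapse, group scales); at desk-scale settings fits are routinely flagged
  `converged = False` by the strict split-R̂ ≤ 1.05 rule even when point
  estimates are stable. Longer chains or the paper-scale settings resolve
  this at proportional cost.
* Hybrid models mixing softmax noise and attitude variability, and
  sequential-sampling extensions using response times, are out of scope.
* The exact allocation values of the nine selfish trials, the original
  trial-presentation order, and the post-experimental questionnaire are not
  reproduced.
* DIC comparisons at small subject counts carry Monte-Carlo noise of a few
  points; the model-recovery test asks for a majority of replicates, not
  certainty, for exactly this reason.
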