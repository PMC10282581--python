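# Methods

## The study being modelled

Four between-subject groups cross **fairness domain** with **conflict
degree**. In the punishment domain the participant repeatedly splits a pot
of points between themself and a person they previously watched behave
unfairly (choosing in favour of the self *punishes* the norm violator); in
the compensation domain the partner is that allocator's victim (choosing in
favour of the other *compensates* them). Every trial also displays a
monetary incentive of 0–500 points that is paid only if the participant
picks the group's incentivized option — either the fairness-congruent one
(*aligned* groups) or the fairness-incongruent one (*conflict* groups).
Each participant answers 120 trials toward the fairness partner and 120
toward an uninvolved baseline partner, preceded by a 20-trial observation
phase (16 of 20 allocator decisions selfish; 8 selfish / 2 generous within
each distribution pairing), 12 practice trials, and 6 hidden control trials
in which one option is better for *both* players. The package's
`synthetic_data` module generates exactly this design: 278 trials per
session, allocation options drawn from 500–700-point pots (step 10) with
self-shares jittered ±5 percentage points around 70:30 (unfair), 50:50
(equal) and 30:70 (hyperfair), and the payout rule
(points_self + matched incentive) × 0.005 €/point plus a 3 € show-up fee.

The binary outcome of every analysis is the **congruence code**: 1 when the
chosen option restores fairness for that group (favour-self in punishment,
favour-other in compensation).

## Drift-diffusion model

A decision is modelled as a Wiener process with drift `v` (evidence
units/s, positive toward the congruent option), boundary separation `a`,
relative starting point `z ∈ (0,1)` and non-decision time `t0`; the
diffusion coefficient is fixed at 1 (a pure scale convention). The
likelihood of a response at boundary b and time t is the first-passage-time
(WFPT) density, computed from the classic small-time and large-time series
expansions with the number of terms chosen by the standard error-bound
criterion at absolute tolerance 1e-7 and the expansion picked where the
term counts cross. The upper boundary is the fairness-congruent option
(stimulus coding). No inter-trial variability parameters (sv, sz, st) are
modelled. Two analytic facts serve as oracles throughout the test suite:
the upper-boundary absorption probability
`(1 − e^{−2vza}) / (1 − e^{−2va})` and the normalisation
∫ f_upper + ∫ f_lower = 1.

The generative simulator is deliberately independent of the density code:
Euler–Maruyama paths (default dt = 1e-3 s) with a Brownian-bridge
boundary-crossing correction, which removes the O(√dt) first-passage bias
of plain Euler stepping; the test suite holds the Kolmogorov–Smirnov
distance to the analytic density below 0.01 at 10⁵ paths. Simulated task
responses slower
than the 4 s deadline are re-drawn, mirroring the task's repeat loop; the
likelihood ignores this truncation — for realistic parameters the
truncated mass is well below 1% and the induced bias is negligible, a
documented approximation.

## Hierarchical estimation

Subject-level parameters (v_i, a_i, logit z_i, t0_i) are drawn from
group-level distributions: Normal for v and logit z (with design covariates
shifting the mean), truncated-positive Normal for a and t0. One `a` and one
`t0` per subject across all conditions. The confirmatory model space is

| model | structure |
|---|---|
| M0 | no covariates |
| V1 | v ~ conflict degree |
| V2 | v ~ conflict degree × fairness domain (free cell means) |
| Z1 | logit z ~ conflict degree |
| Z2 | logit z ~ conflict degree × fairness domain |

The two-factor models carry the interaction column — i.e. one free group
mean per condition cell — matching the per-condition estimates of the
reference hierarchical-DDM convention; a purely additive two-factor model
would make the domain-difference contrast (H6 below) identically zero and
untestable. The exploratory ZI model regresses logit z on the trial-wise
incentive level (coded points/100, 0–5) and is fitted per group with v
free.

Priors are weakly informative: group means Normal(0, 2) for v and its
effects, Normal(1.5, 0.75) for a, Normal(0, 1) on logit z, Normal(0.4, 0.2)
for t0; all group scales Half-Normal(0.5); incentive-bias weight
Normal(0, 1).

Sampling is adaptive Metropolis-within-Gibbs: component-wise random-walk
proposals for every subject-level parameter and for the truncated-normal
and scale hyper-parameters, with per-parameter proposal scales tuned toward
44% acceptance in blocks of 25 iterations during burn-in (Robbins–Monro,
frozen afterwards so the post-burn-in chain is Markovian), and exact
conjugate Gibbs draws for the Normal location/regression coefficients of v
and logit z. Defaults are 4 chains × 5000 draws after 2000 burn-in
iterations, no thinning; every fit is reproducible from its seed.
Convergence is gated on the split Gelman–Rubin statistic of all group-level
parameters (R̂ < 1.01, computed with arviz and cross-checked in the tests
against the classic formula); Geweke z-scores are available as a secondary
diagnostic. A non-converged fit is returned flagged with a warning, never
silently.

## Model comparison and hypothesis tests

The deviance conditions on the subject-level parameters (lowest-level
focus): D = −2 Σ_i log L_i. Then pD = D̄ − D(θ̄) with θ̄ the posterior mean
of the subject-level parameters, and DIC = D̄ + pD. Selection uses the
ΔDIC-10 rule with lower-is-better orientation: the minimum-DIC model wins
outright when every competitor is ≥ 10 DIC above it; otherwise all models
within 10 of the minimum form an averaging set whose traces are pooled with
weights ∝ exp(−ΔDIC/2), the member model drawn once per posterior draw so
within-draw contrasts are preserved. A member without a given effect
contributes its null (exactly tied) cells, which count toward neither
direction of a directional test.

Directional hypotheses are posterior exceedance probabilities — the
fraction of paired draws in which one parameter exceeds another —
"significant" above 95%:

* **H4** conflict slows congruent accumulation: a V model among the winners
  and P(v_aligned > v_conflict) > 0.95;
* **H5** conflict shifts the start away from the congruent option: a Z
  model among the winners and P(z_aligned > z_conflict) > 0.95;
* **H6** the conflict effect differs between domains: V2 and/or Z2 among
  the winners and the double difference
  (aligned − conflict)_punishment − (aligned − conflict)_compensation
  exceeding zero with > 95% probability in either direction.

## Logistic mixed models

The confirmatory model on fairness-partner trials is

    response ~ conflict_degree * fairness_domain
               + conflict_degree * incentive_level + (1 | participant)

with treatment coding (aligned and compensation as references) and
incentive in units of 100 points (0–5), so coefficients read "per 100
points". Estimation is maximum likelihood with the random intercept
integrated out by adaptive Gauss–Hermite quadrature (15 nodes by default;
1 node is the Laplace approximation), Newton-optimised cluster modes, and
Wald z = β/s.e. from the numerical Hessian at the optimum. On a small
study this estimator agrees with lme4's `glmer` to ~1e-5 in coefficients
(the test suite keeps that cross-check). When the variance estimate
collapses to the boundary the fit reduces to ordinary logistic regression
and is flagged.

Quality control mirrors the study: a participant is excluded when they
choose the dominated option in ≥ 2 of 6 control trials or their mean RT is
below 500 ms; excluded participants are removed entirely and control (and
practice) trials never enter analysis tables.

The manipulation-check family contains (i) a per-domain model
response ~ partner × conflict with a by-participant random slope over the
distribution-type factor, delegated to lme4 through Rscript (the only
multivariate random effect in the package); a singular or failed slope fit
triggers a flagged refit with the in-package random-intercept estimator.
In this synthetic design the distribution-type factor has the two levels
the decision task actually shows (unfair-vs-equal, hyperfair-vs-equal).
(ii) decision ~ domain × partner and (iii) decision ~ domain × incentive
type, both random-intercept models. Trait scores are Pearson-correlated
(Spearman available) with per-group congruent rates, Bonferroni-corrected
by factor 5 (the five scales tested per group).

## Synthetic participants

The diffusion generator draws per-subject parameters around
a ≈ N(1.6, 0.15), t0 ≈ N(0.35, 0.05), z from logit-Normal(0, 0.2), and
drift v = 0.6 + 0.3·[punishment] − 0.8·[conflict] + 0.15·[fairness partner]
+ N(0, 0.3) toward the congruent boundary — values chosen once to mimic the
qualitative pattern of the study's findings (congruent drift reduced under
conflict, larger in punishment, RTs well inside the 4 s window) at
realistic online-study magnitudes. The logistic generator uses the
study's planning probabilities (favour-other 65% compensation / 45%
punishment), incentive weights 0.25 (conflict punishment) / 0.15
(elsewhere) per 100 points toward the incentivized option, a participant
intercept s.d. of 1, and a 0.15-logit norm-activation bonus toward the
congruent option for fairness-partner trials. Control trials are answered
correctly with probability 0.98 (configurable; careless participants answer
at chance and fast, for exercising the filters). Trait scales mimic the
named instruments' ranges only; `js_perpetrator` is coupled to congruent
behaviour through a Gaussian copula so a target correlation is recovered
exactly in expectation.

What the generator does **not** emulate: sequential dependencies, learning
or fatigue, RT contaminants (anticipations, lapses), item-level
questionnaire structure, observation-phase fairness ratings, and any
real-participant heterogeneity beyond Normal random effects. Passing tests
therefore demonstrate correctness of the machinery on data satisfying the
model's assumptions, not robustness to real-data violations.

## Power analysis

The power module replicates the study's sample-size planning: simulate
complete four-group studies (30 per group, 120 fairness-partner trials)
from the logistic generative model, fit the confirmatory GLMM, and count
p < 0.05 per fixed effect over 100 simulations, with Clopper–Pearson 95%
intervals.

One generative choice requires justification: the power generator draws
independent Bernoulli responses with **no participant random intercept**
(σ_u = 0), although the analysis model estimates one. The domain × conflict
interaction is a between-subject double difference across four groups of
30, so its standard error is about √(4(σ_u² + 1/(m·p(1−p)))/30); any
appreciable generative σ_u (say 0.5–1) would push it to ≈ 0.2–0.4 logits
against a true projected effect of ≈ −0.25 and cap power far below the
level this design is known to achieve — the reported high power for that
interaction is only arithmetically possible when between-subject
heterogeneity is an analysis-model, not a data-generating, feature. With
σ_u = 0 the package's acceptance run measures ≈ 93% power for domain ×
conflict and 100% for conflict × incentive at this configuration. σ_u
remains configurable
(the general-purpose study simulator keeps σ_u = 1 as its default).

## Numerical choices and degenerate inputs

* WFPT series tolerance 1e-7; negative truncation residue clipped to 0;
  densities at t ≤ t0 are exactly 0 and any observed rt ≤ t0 yields a
  flagged −inf log-likelihood rather than an exception.
* Path simulator dt = 1e-3 s with bridge correction (1e-4 available where
  extra accuracy is wanted).
* Exceedance uses strict inequality; exactly tied draws support neither
  direction.
* DIC's θ̄ uses natural-scale posterior means of (v, a, logit z, t0) per
  subject.
* GLMM: L-BFGS-B on (β, log σ_u) with log σ_u bounded in [log 1e-5,
  log 50]; central-difference Hessian with step 1e-4; a boundary σ̂_u is
  flagged and the Wald covariance then comes from the β block alone.
* Allocation rounding: shares are drawn uniformly in the band, rounded to
  integer points, then clamped back into the band (rounding can otherwise
  cross the edge by < 0.1 percentage points).
* Stage seeds derive from SHA-256 of (master seed, stage name), mod 2³¹.

## Problem sizes used by the test and acceptance runs

Simulation-based checks run at sizes chosen to make each property
detectable with comfortable margin: parameter recovery and model recovery
use 32 subjects × 120 trials with 2 chains × (400–800 draws); model
recovery uses deliberately strong drift effects (conflict −1.5, domain
+0.8) over 3 replicates; the single-subject consistency check uses 3000
trials; GLMM type-I calibration uses 40 null replicates at the full 120
participants (× 60 trials) because Wald z-tests on between-subject effects
are only calibrated with many clusters; the power replication uses the
full planning configuration (120 × 120) at n_sims = 100. The full-study pipeline default remains the complete design
(4 × 30 participants, 4 × 5000-draw chains).

## Known limitations

* The sampler is random-walk based; for much larger designs a
  gradient-based sampler would mix faster. Convergence at the default
  settings should always be checked via the reported R̂ values.
* DIC with subject-level focus discriminates between-subject covariate
  structures only through shrinkage, so ΔDIC values on small synthetic
  designs are modest; the selection rule's 10-point margin is inherited
  from the study, not re-derived.
* The deadline-truncation approximation above; no RT outlier mixture.
* lme4 is required only for the random-slope manipulation model; without a
  working Rscript that model falls back (flagged) to a random-intercept
  structure.
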