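# Methods

## The task and the generative model

`stopddm` models a temporal-prediction stop-signal experiment. On every
trial a disc moves toward a stationary one and "collides" with it 1000 ms
after motion onset. On **go trials** the subject presses a key at the
predicted collision moment; the temporal estimation error (TEE) is
`RT − 1000 ms`, with `TEE ≤ 0` counted as an early response. On **stop
trials** (a quarter of trials) a colour change presented at the
stop-signal delay (SSD) after motion onset instructs the subject to
withhold the press. The SSD follows a symmetric 1-up/1-down staircase
with a 30 ms step: up after a successful stop, down after a failed one.
A symmetric fixed-step staircase equilibrates where the probability of
responding is 50%, so the mean presented SSD estimates the subject's
SSD50.

The go process is a **one-choice drift-diffusion**: evidence accumulates
with drift `v` from starting point `z·a` toward a single threshold `a`
(diffusion coefficient fixed at 1, which sets the scale of `a` and `v`).
Its first-passage time is Wald (inverse-Gaussian) with mean
`μ = a(1−z)/v` and shape `λ = (a(1−z))²`, shifted by the non-decision
time `t`; the observed mean RT is `t + a(1−z)/v`. `z` is *relative* — a
fraction of `a` — which is the only reading under which starting points
of ~0.3–0.4 are commensurate with thresholds of ~9. A larger `z` (a
stronger prior commitment to respond) shortens the distance to threshold
and produces earlier, more premature predictions. No inter-trial
variability parameters are included.

The stop process is phenomenological: a latency (SSRT) drawn per stop
trial from a normal distribution truncated at zero (defaults: mean
300 ms, SD 50 ms; pluggable per group). The **independent horse race**
decides the outcome: the response is inhibited iff
`RT_go > SSD + SSRT`; ties respond. Because the simulator draws the go
RT on every trial whether or not a stop signal occurs, context
independence holds by construction, and signal-respond RTs are the go RT
distribution censored from above — hence their mean is smaller.

Internal DDM computations are in seconds; trial tables and all task
timeline quantities are in milliseconds, converted exactly once at the
trial-record boundary.

## Synthetic cohorts

The default cohort has two arms of 15 subjects, five blocks of 30 go +
10 stop trials each (a familiarization block is not simulated; no
analysis would use it). Subject parameters are drawn from normals
truncated to each parameter's domain. Defaults: the arms share
`a = 8.86`, `v = 8.48`, `t = 0.28 s`, and differ only in the starting
point (`z = 0.43` vs `0.30`, both with between-subject SD 0.12) and the
stop latency mean (309 vs 276 ms). Between-subject SDs for the shared
parameters are `a`: 1.0, `v`: 0.2, `t`: 0.05 s. The SDs for `a` and `t`
are this package's choices: reading the much larger spreads sometimes
quoted for these parameters as *generative* between-subject SDs would
imply trial-level RT spreads far wider than the RT summaries they
accompany (a near-zero threshold subject, or non-decision times longer
than the mean RT), so moderate values consistent with ~30–180 ms
group RT SDs were fixed once and kept.

Staircase defaults the task timeline does not pin down: initial SSD
500 ms (between the two arms' equilibrium SSD50s), SSD clamped to
[30, 2400] ms, carried continuously across blocks rather than reset.
Stop-trial positions are drawn uniformly within each block without
adjacency constraints. The simulator never drops records: overlong go
RTs are written out and excluded downstream, with a logged count. The
simulator cannot produce negative RTs (responses before motion onset);
the exclusion filter still handles them on ingested data.

## Exclusion and behavioral statistics

Go trials with `RT > 1250 ms` or `RT < 0 ms` are excluded (strict
inequalities; the filter is idempotent and never mutates its input).
Group aggregates summarize |TEE|, go RT, signal-respond RT and
inhibition accuracy over trials, and SSD50 / mean-method SSRT
(`mean RT_go − SSD50`, computed per subject after exclusion) over
subjects.

Group comparisons are deliberately **two-stage**: subject means compared
with ordinary two-sample t statistics (Welch or pooled; both exposed) and
a paired t for the signal-respond vs go contrast. Mixed-effects models
with subject random effects would be the textbook alternative; at the
cohort sizes involved the two-stage route reproduces the same
fixed-effect directions, and every report emitted labels the method.
p-values are not computed — the statistic and its degrees of freedom
carry the content.

## Hierarchical Bayesian fits

Only responded, post-exclusion go RTs enter the likelihood. Subject
parameters follow truncated-normal group distributions; model variants
declare which group *means* differ (model 1: z and v; 2: z; 3: v; 4: a;
0: none). Between-subject SDs are shared across groups; `t` is never
group-split. Priors (all overridable): group means `a ~ N(5, 5²)` on
(0, ∞), `z ~ N(0.5, 0.25²)` on (0, 1), `v ~ N(5, 5²)` on (0, ∞),
`t ~ N(0.3, 0.3²)` on [0, ∞); between-subject SDs half-normal with
scale 1 (0.2 for z). These are weakly informative at the scale of the
task.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs, with proposals on log
scales for `a` and `v`, the logit scale for `z`, natural scale for `t`.
The shifted-Wald likelihood identifies, per subject, essentially
`(μ, λ, t)` — three functions of four parameters — so the posterior
contains ridges that single-site updates cannot cross. Dedicated joint
proposals walk them explicitly, with exact Jacobians:

* **(a, z) ridge** — rescale `a` and `1−z` oppositely, holding
  `a(1−z)` (hence the whole likelihood) fixed; per subject, per group
  (carrying the group's z mean along), and globally (carrying the a/z
  hyperparameters);
* **(t, v) shift** — trade non-decision time against the Wald mean at
  fixed `a(1−z)`, holding each subject's mean RT fixed;
* **(t, a, v) skew** — shift `t` while rescaling `a` and `v` so each
  subject's RT mean *and* variance stay fixed; only the skewness
  changes, which is all the data have left to say about `t`. Applied
  per subject and globally (translating the `t` hierarchy).

Correctness of these moves was checked by comparing the posterior from
the full sampler against a long run with all joint moves disabled on a
small single-subject problem: the marginals agree within Monte-Carlo
error.

Proposal scales adapt toward ~30% acceptance during a dedicated warm-up
phase and are frozen before the retained run, so the nominal burn-in of
the retained chain (default 10,000 draws, first 200 discarded) is
honest. Default 4 chains; split-R̂ (computed on half-chains, so it is
defined even for one chain) and effective sample sizes are always
reported, and a fit with any group-level R̂ > 1.1 is flagged, never
suppressed. Subject `t` is initialized safely below each subject's
minimum RT; the likelihood is −∞ beyond it, so proposals cannot cross.

### DIC and posterior proportions

Deviance is −2 × the total go-trial log-likelihood.
`pD = mean deviance − deviance at the posterior means`,
`DIC = mean deviance + pD`; lower DIC wins. The plug-in point for `pD`
is formed in the likelihood's identified coordinates — posterior means
of `log a(1−z)`, `logit z`, `log v` and `t`, with `a` reconstructed as
`a(1−z)/(1−z)` — because averaging the raw `a` and `z` draws places the
point off the curved `a(1−z)` ridge, which in testing produced large
negative `pD` and ±35-unit run-to-run DIC jitter on identical data. The
posterior proportion (PP) for a group-varying parameter is the fraction
of retained draws in which one group's mean exceeds the other's.

### Identifiability, and what recovery does and does not show

With realistic trial counts the skew-only information about `t` is weak:
the posterior spreads along the (t, a, v) ridge, and under the default
weakly informative priors the *level* of the hierarchy can settle well
below the generating `t` (the prior on the between-subject z SD rewards
configurations with larger `a`, where subject z values cluster more
tightly). Two consequences are documented rather than hidden:

* Group-level **contrasts** in `z` — the difference and its posterior
  proportion — are recovered reliably; the absolute z *levels* ride the
  ridge and can be biased by ~0.05–0.1 at the default cohort size, with
  correspondingly wide posterior spreads on `a` and `t`. Tightening the
  `t` prior threefold was tested and does not repair level recovery,
  because the binding freedom is the `a`-vs-`z` allocation itself; the
  default priors are therefore kept.
* The same fact bounds what **DIC model selection** can do here. A group
  difference in `z` (model 2) and a group difference in `a` (model 4)
  generate *identical* families of go-RT distributions — both move the
  distance-to-threshold by group — and the z+v model nests the z-only
  model. Under symmetric weakly informative priors the four variants
  therefore differ by only a few deviance units of prior structure,
  which is inside DIC replicate noise: on synthetic z-difference data
  the DIC winner scatters across the variants rather than repeatedly
  picking the z-only model. Published analyses of this family that
  report decisive DIC gaps between these variants are, in effect,
  leaning on informative threshold priors in their fitting tooling;
  with the neutral priors used here the honest statement is that
  one-choice go-RT data cannot separate a starting-point account from a
  threshold account. The shared-vs-group-varying distinction (model 0
  against the rest) and the drift-only model's inability to reproduce a
  group difference in the Wald shape remain testable.
* Spiegelhalter's `pD` is computed at a plug-in point formed in the
  identified coordinates (see above); with the raw-scale plug-in it went
  strongly negative and made DIC irreproducible. Even so, model-recovery
  behavior is assessed over seeded replicates, never a single fit.

## Problem sizes used in the test suite

Full-scale parameter recovery uses the default cohort (15+15 subjects,
150 go trials each) with 10,000 retained samples. Model-recovery
replication uses scaled-down cohorts (8 subjects/arm, 60 go trials each)
with shorter chains, which keeps the whole replication affordable on a
single CPU; the methods above are unchanged by the scaling. The
staircase-convergence checks use ≥10,000 stop trials with the first 500
discarded.

## Known limitations

* The generator emulates the task's trial structure and race logic, not
  display-level details (fixation jitter, stimulus rendering) nor
  anticipatory negative-RT artifacts of real button boxes.
* Real go-RT distributions can be left-skewed (e.g. by a deadline-aware
  slowing of late responses); the pure shifted-Wald go process is
  right-skewed by construction, and the tests assert exactly that — so
  passing tests say nothing about mean-method SSRT reliability under
  left skew.
* The integration-method SSRT estimator is not implemented (the race
  summaries expose mean-method only).
* Mixed-effects regressions are replaced by two-stage tests, as above.
* DIC values from different datasets are not comparable; only
  within-dataset model ranks are meaningful here.
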