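# Methods

## Task environment

The two-step task is modelled with a single first-stage state (two actions)
and two second-stage states (two actions each). Action *a* at stage 1 leads to
second-stage state *a* with probability `p_common = 0.7` ("common"
transition) and to the other state otherwise ("rare"). The transition
structure is fixed and — following the instruction protocol of the paradigm —
known to the agent's planner; it is not learned.

Reward probabilities of the four second-stage stimuli follow independent
Gaussian random walks with per-trial step SD 0.025, reflected at
[0.25, 0.75]. The paradigm's published description fixes neither the bounds,
the step size, nor the initial values; we adopt the original task's
convention for bounds and step SD and draw the initial probabilities
uniformly within the bounds from the walk seed. One walk realization is
generated per cohort and shared by all subjects, as in the experiment. A
consequence worth noting: the time-average of a single 201-trial walk
realization has an SD of roughly 0.03–0.05 around 0.5, so cohort-level mean
accumulated reward varies by ±10–20 rewarded trials purely with the walk
seed. Rewards are coded 0/1; the monetary framing of the original experiment
is presentation only.

## Agent

The hybrid agent combines:

* **Model-free SARSA(λ).** Stage-1 values are updated with learning rate α₁
  toward the visited second-stage value (δ₁), and additionally by the
  stage-2 reward prediction error δ₂ scaled by α₁λ. Stage-2 values are
  updated with α₂. Only visited state–action entries change.
* **Model-based planner.** Q_MB(s_A, a) = P(common)·max_a' Q₂(common(a), a') +
  P(rare)·max_a' Q₂(rare(a), a'), recomputed from the current stage-2 values
  on every trial.

First-stage decision values are Q_net = ω·Q_MB + (1 − ω)·Q_MF; at stage 2 the
two systems coincide. Choice probabilities are softmax with inverse
temperatures β₁, β₂ and a first-stage perseveration bonus ρ·rep(a), where
rep(a) = 1 if a repeats the previous first-stage choice (0 on the first
trial). There is no perseveration at stage 2. All Q values start at 0 — not
part of the published description, but the standard convention for this task
family. The likelihood of an observed session replays exactly the same
updates with the observed choices and outcomes and accumulates
−log p(choice) over both stages (guarded by max-subtraction in the softmax
and a 1e-300 floor before the log). The per-trial loops are numba-compiled;
a pure-Python trace (`likelihood_trace`) exposes per-trial probabilities for
debugging and is tested to agree with the compiled path.

### Model variants

Five variants are distinguished by pinning ω and λ: the full hybrid (7 free
parameters); the hybrid with λ = 0 (6) — the published label for this variant
is ambiguous, and we read it as λ fixed with ω free; the pure planner ω = 1
(4: α₂, β₁, β₂, ρ — with ω = 1 the stage-1 model-free values never reach the
softmax, so α₁ and λ are inert and are not fitted); pure model-free ω = 0
with λ (6) and without λ (5).

## Hierarchical fitting

Free parameters are optimised in unconstrained coordinates: logit for
α₁, α₂, λ, ω; log for β₁, β₂; identity for ρ (the published transform list
omits ρ; identity keeps it unbounded, consistent with its small fitted
values, and gives it a plain Gaussian prior).

**E-step.** Each subject's MAP estimate minimises
−log L(θ) + ½Σ(θ−μ)²/σ² by L-BFGS-B from up to 5 starts (the previous
iteration's optimum as warm start, the prior mean, and prior-scaled jittered
draws; all seeded). The Hessian of the penalised objective is computed by
central finite differences (step 1e-3) and inverted (pseudo-inverse
fallback) for the Laplace covariance.

**M-step.** Prior means are the average MAP estimates; prior variances are
the between-subject spread plus the average Laplace variance
(σ²_k = mean(θ²_ik + Σ_i,kk) − μ²_k), floored at 1e-6. EM stops when the
largest absolute change in prior means falls below 1e-3 (default; at most
100 iterations). A Laplace approximation of the cohort's negative log
marginal likelihood is recorded per iteration; it decreases monotonically up
to small numerical bumps (the variance floor and finite-difference Hessians
break exact monotonicity), which the tests check.

**Model evidence.** iBIC = −2·Σᵢ log p̂(sessionᵢ | prior) + 2·d·log N, where
d is the number of free parameters (two hyperparameters each) and N the
total number of observed choices (two per trial — both stages count).
log p̂ is a Monte-Carlo average of the session likelihood over 2000 prior
draws (log-sum-exp; one fixed, seeded draw set shared across subjects —
unbiased, cheaper, and lower-variance for model *differences*). A Laplace
alternative is available (`method="laplace"`) and agrees with the MC route
within a few percent in the tests. Per-group iBIC scores restrict both the
evidence sum and the penalty's observation count to the group.

## Stay-probability statistics

Trial *t* ≥ 1 counts as a "stay" iff the first-stage choice repeats trial
*t*−1's; it is assigned to the cell given by trial *t*−1's reward and
transition. The first trial has no predecessor and is dropped; empty cells
are NaN and flagged, never coerced to 0. Contrast scores per subject:
interaction (RC−RR)−(UC−UR), reward main effect (RC+RR)−(UC+UR).

The Group × Reward × Transition mixed ANOVA is computed by reducing the
split-plot design to orthonormal per-subject contrast scores (cell mean,
reward, transition, interaction — coefficients ±½). Because both
within-subject factors have two levels, this reduction is exact (and makes
the univariate/multivariate distinction moot): each within effect and its
Group interaction become type III tests (sum-to-zero coding, statsmodels
OLS) on one score, with the intercept testing the unweighted grand mean.
The implementation is validated against an independent R `car::Anova`
repeated-measures oracle and against the one-way F on the raw contrast
terms (equal to 1e-8). Partial η² = SS_effect/(SS_effect + SS_error) within
each stratum.

Planned pairwise group comparisons are equal-variance two-sample t-tests
without multiplicity correction (matching the df pattern of group sizes
31/29/30). Kruskal–Wallis uses midrank tie correction;
η²_H = (H − k + 1)/(n − k). The BMI analysis regresses a per-subject measure
on orthonormal degree-2 polynomial predictors of BMI (QR-orthogonalised,
signs fixed, zero mutual correlation by construction) and reports
standardized coefficients, per-coefficient p, adjusted R² and the overall F.
Shapiro–Wilk and Levene screening is exposed as a utility; routing to
parametric versus rank tests is left to the caller, since that choice is
per-measure.

## Synthetic cohorts

`default_cohort_spec()` emulates the reference study's design: groups NW/OW/OB
of 31/29/30 subjects, BMI drawn uniformly within 18.5–24.9 / 25–29.9 /
30–47.6 kg/m², 201 trials, one shared walk per cohort, and per-subject
parameters drawn from group Gaussians in transformed space centred on the
published per-group fitted means and SDs (the obese group's ω mean, 0.60,
sits below the other groups' 0.66/0.68).

Natural-space (mean, SD) pairs are converted to transformed-space moments as
follows. Logit parameters: mean through the logit (median matching), SD by
the delta method — the induced mean bias is far below one standard error at
the published spreads. Log parameters (β₁, β₂): exact lognormal moment
matching, μ = log(m²/√(m²+s²)), σ² = log(1+(s/m)²), so the implied
natural-space mean and SD equal the targets; pure median matching would
inflate E[β₂] by more than one standard error in the obese group, whose
coefficient of variation is large. ρ passes through unchanged.

What the generator does *not* emulate: real BMI histograms (uniform within
range), any continuous BMI→behaviour link (the planted effect is
group-mean-based; a linear-in-BMI ω gradient can be built by overriding
group means), reaction times, questionnaire scores, or session-to-session
non-stationarities (fatigue, attention lapses). Passing tests on these
cohorts therefore certify the *pipeline* — likelihood, fitting, statistics —
under the model's own assumptions, not the empirical effect sizes of any
human sample. Indeed, generating cohorts exactly at the published group
parameter moments produces a mean behavioural interaction-term gap of only
≈0.05 between the obese and the other groups — roughly a third of the gap
the original behavioural data showed — so a significant three-way
interaction is obtained in only a minority of replicate cohorts at n = 90,
and empirical-Bayes shrinkage (one shared prior, as in the original
analysis) compresses it further in posterior-predictive re-simulation. The
end-to-end simulation-recovery test asserts the strict criterion and is
expected to fail at typical seeds; the accompanying suite documents the
attenuation rather than hiding it.

Posterior-predictive checks re-simulate each subject from their MAP estimate
(default 1000 sessions per subject; reduced counts are used in tests),
average each subject's stay cells across simulations (NaN cells ignored) and
re-run the mixed ANOVA. Parameter recovery reports bias, RMSE and Spearman
rank correlation between generating and recovered values. At the study's
scale (90 subjects × 201 trials, published parameter spreads) the rank
correlation for ω is ≈0.5 — the task's known identifiability limit at this
session length — rising above 0.9 for near-greedy agents on long sessions
(β ≈ 20, 2000 trials).

## Problem sizes and determinism

Test and acceptance runs scale replicate counts to desk scale: EM uses 2–3
restarts and 10–20 iterations in tests (5/100 defaults in the API), iBIC
model recovery uses 12-subject, 140-trial cohorts with 3 replicates per
generating model, the null-calibration check uses 100 effect-free cohorts,
and posterior prediction uses 100 simulations per subject. Every stochastic
stage takes an explicit integer seed; cohort generation, fitting and
simulation are bit-reproducible given the seed and library versions. Known
limitations: no transition-matrix learning, no reaction-time or
drift-diffusion modelling, no forgetting/decay variants, and no MCMC
posteriors (MAP + Laplace only).
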