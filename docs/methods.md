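# Methods

## Task generative process

Blocks pair two arms with true means drawn i.i.d. from N(prior_mean = 0,
prior_var = 100) points². Arm labels follow the block condition (RS, SR,
RR, SS); each 4-block run contains every condition exactly once in
seeded-shuffled order, 8 runs per subject. Risky arms pay N(μ, 16)
points; safe arms pay μ exactly — the safe pseudo-variance 10⁻⁵ points²
exists only inside the observer's Kalman update, where it prevents a
degenerate (zero-gain) step while still collapsing the posterior onto μ
after a single sample. Rewards are kept continuous (a `round_rewards`
flag rounds to integer points; off by default, since display rounding is
a presentation detail). Timeouts are not generated by default; a
`timeout_rate` flag drops a random fraction of responses to exercise
missing-data handling — timeout trials carry regressors but no choice,
reward or belief update, the only coherent treatment given that no
feedback is shown.

Seeding: every stochastic component consumes a named `SeedSequence`
substream of one master seed — per-subject task streams (so subject k's
bandits are identical regardless of how many subjects are generated) and
separate per-subject choice streams. All outputs are bit-reproducible
from the configuration.

## Ideal observer

Gaussian rewards with fixed within-block means make the Kalman filter the
exact Bayesian belief update; the posterior variance after n observations
of an arm obeys the conjugate closed form 1/(1/τ₀² + n/τ²), which the
tests verify to 1e-9. Regressors (V, RU, TU, V/TU) are always computed
from the belief *before* the trial's outcome, because the choice model
predicts the choice from pre-choice beliefs. Beliefs reset at block
starts. On SS blocks TU falls to √(2·10⁻⁵) ≈ 4.5·10⁻³ once both arms
have been sampled, so V/TU legitimately reaches ±10³; no clipping is
applied at this stage — downstream consumers handle the scale.

## Choice models and fitting

The hybrid probit P(a=1) = Φ(w₁V + w₂RU + w₃V/TU) and its lesioned
variants (value-only, UCB = {V, RU}, Thompson = {V/TU}) share one fitting
path. Choice probabilities are clipped to [1e-10, 1−1e-10] when evaluated
as probabilities; the likelihood itself is computed through `log_ndtr`,
which is finite and accurate in both tails without clipping.

Per-subject/pooled ML uses a damped Newton optimiser with the analytic
probit gradient and Hessian (the Hessian weight r(r+z) with r the inverse
Mills ratio is strictly positive, so the negative log-likelihood is
convex). Design columns are rescaled to unit RMS internally — the MLE is
exactly equivariant under column rescaling — which keeps the Newton
system well conditioned despite the 1e3-scale V/TU column. Two
deterministic starts (origin and a small perturbation) guard the line
search. Convergence: max |gradient| per observation ≤ 1e-8, or a step
below machine precision. Complete separation (every observation predicted
with strictly positive margin and near-zero deviance) is flagged as a
warning rather than allowed to diverge; standardised weights are hard-
capped at 1e8. Standard errors come from the inverse observed information
at the optimum; p-values are Wald tests against the standard normal.

The mixed-effects fit maximises a Laplace approximation of the marginal
likelihood of choiceᵢₜ ~ Bernoulli(Φ(xᵢₜ'(β + bᵢ))), bᵢ ~ N(0, diag(s²)):
inner Newton iterations find each subject's posterior mode (warm-started
across outer iterations), the outer L-BFGS-B moves (β, log s²). The
per-subject conditional modes β + b̂ᵢ are exposed as subject-specific
coefficients — these are what the decision value DV = w₁V + w₂RU + w₃V/TU
uses when computed per subject. With one subject the function returns the
fixed-effects ML fit. This mirrors the standard Laplace GLMM procedure
without attempting to replicate any particular package bit-for-bit.

The condition model Φ(Σⱼ w₁ʲπₜⱼ + w₂ʲπₜⱼVₜ) is fit per subject on the
8-column one-hot design; the summary reports cross-subject means and
standard errors, which is how the behavioural signatures (risky-arm
intercept shift on RS/SR; slope reduction on RR vs SS) are assessed.
Conditions absent from a subject's data give NaN estimates and are
flagged.

Model comparison approximates each subject's log evidence as −BIC/2 from
the fixed-effects fit and runs random-effects Bayesian model selection:
variational Dirichlet updates (prior α₀ = 1) for the population model
frequencies, exceedance probabilities by 10⁶ seeded Dirichlet draws
(exact Beta tails when only two models), the Bayes omnibus risk from the
free energy of the random-effects model against the equal-frequency
null, and protected exceedance probabilities
PXP = (1−BOR)·EP + BOR/K.

## Parameter recovery and its limits

Each recovery simulation draws one weight vector from N(0, 10·I),
simulates the full 31-subject experiment on fresh bandits, and refits by
pooled probit ML (a hierarchical refit is available behind a flag at
reduced simulation counts; the recovered quantity is the population
weight vector either way, and the pooled fit is ~100× faster).

A property of this experiment worth stating plainly: with weight
magnitudes ~√10 ≈ 3.2 on the raw regressor scale, the simulated linear
predictor exceeds ±8 on nearly every trial after the first of each
block, so simulated choices are deterministic and the likelihood is flat
(to machine precision — observed-information eigenvalues below 1e-11)
over an unbounded region of weight space. Only the weight *signs* are
identified there; no fitting procedure can recover the magnitudes, and
recovered V and V/TU weights trade off freely along the flat ridge.
Generated-vs-recovered correlations in this regime are therefore far
below 1 (and recovered-weight pairs can correlate strongly), whereas at
the weight scale actually observed in human subjects (~0.17, 0.18,
0.005) the likelihood is sharply curved and the same pipeline recovers
weights within a few standard errors (verified in the unit tests, and
independently cross-checked against statsmodels' probit). The recovery
experiment at the N(0, 10·I) scale is retained as specified; its outputs
should be read with this identifiability caveat in mind.

## Synthetic neural panels and decoding

A region's signal is modelled at the trial level: y_t(voxel) =
Σᵢ X_{t,i} βᵢ + N(0, noise_sd²), with named design columns |RU|, TU,
|V|, |V|/TU, |DV| (plus arbitrary nuisance columns) and known per-voxel
β. This abstracts away haemodynamics deliberately: the decoding algebra
is identical with or without an HRF, and the package makes no claim
about BOLD time-series estimation. Consequences for interpretation:
passing tests show the decoding/augmentation logic is correct given
trial-level signals with known β; they say nothing about HRF
deconvolution, autocorrelated scanner noise, or motion artefacts in real
data.

Decoding inverts the generating GLM one regressor at a time with a ridge
penalty λ (default 1, configurable):
est_t = (y_t − Σ_{i≠target} X_{t,i}βᵢ)·β_target/(β_target² + λ), per
voxel, then averaged across voxels; magnitudes are averaged before the
sign is restored from the model-based series (+|est| when the model
value ≥ 0, −|est| otherwise). The noiseless λ=0 decode is exact; with
λ > 0 the decode is attenuated by exactly β²/(β² + λ), which tests
verify analytically. Decoded TU is floored at 1e-6 before dividing V, a
documented convention for a quantity the model requires to be positive.

Augmented choice models add the decoded series (plus an intercept w₀,
which the baseline also receives) and are compared to the baseline by
ΔAIC/ΔBIC/Δdeviance; perfect collinearity between a decoded column and
its model-based counterpart is detected and flagged.

The `thompson-sample-DV` generative mode implements the sampling account
of random exploration: the decision-value signal on each trial uses the
sampled value difference Q̃(1) − Q̃(2) ~ N(V, TU²) in place of its
expectation, adding noise w₃·(Q̃-diff − V) ~ N(0, w₃²TU²) on top of the
mean |DV| signal (shared across the region's voxels, as one sample per
decision). Squared GLM residuals therefore scale with TU² by
construction, and the Fisher-z group t-test on corr(resid², TU²) is
positive in this mode and at null rates in the closed-form mode.

## Problem sizes and defaults

Defaults reproduce the study conditions: 31 subjects, 8 runs × 4 blocks
× 10 trials, prior variance 100, risky variance 16, safe pseudo-variance
1e-5, recovery prior N(0, 10·I) with 1000 simulations in the acceptance
script, ridge λ = 1, 10⁶ Dirichlet draws for exceedance probabilities.
Tests exercise the same machinery at reduced scale chosen to keep each
check's Monte-Carlo error well inside its assertion margin: 2-60
simulated subjects for unit tests, 200 subjects for the behavioural-
signature check, 31 for model comparison and the residual-variance test,
100 recovery simulations in the suite against 1000 in the acceptance
script, and a 2-4 point performance grid standing in for the full
16-point surface (the surface is available at full scale through the
`gridperf` CLI). The explicit-UCB bonus coefficient defaults to 1; it is
defined only up to proportionality and is absorbed into w₂ in the probit.

## Known limitations

- No reaction-time modelling (sequential-sampling accounts are out of
  scope), no meta-decision between strategies, no more-than-two-arm
  generalisation.
- The neural panel is a trial-level abstraction; nothing here estimates
  GLMs on real BOLD data.
- The hierarchical fit uses a diagonal random-effect covariance and a
  Laplace approximation; full MCMC posteriors are out of scope.
- Parameter recovery at the N(0, 10·I) weight scale is limited by the
  task's intrinsic identifiability, as described above.
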