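# Methods

## Model

`sathmm` fits an input–output hidden Markov model to sequences of
item-difficulty choices from a self-adapted test.  Choices (levels 1–7,
analyzed as y = level/7) are conditionally independent univariate Gaussians
given a latent first-order Markov chain with M states; both the initial-state
distribution and the per-item transition matrix are multinomial-logistic
functions of observed covariates, so the transition matrix varies by
participant and item.  Treating the 7-point ordinal scale as continuous is a
deliberate approximation (standard practice for ordinal scales with five or
more categories); its cost shows up as mild discretization bias, quantified
below.

Covariates: the initial-state design is (d, p, dp), where d is the goal
condition (1 = performance, 0 = learning) and p the pre-test proportion
correct in [0, 1]; the transition design is built from d and the accumulated
correctness r and confidence f (running means on [0, 1]) with all two- and
three-way products.  One latent class is the reference class, its logit
column pinned to zero.

### Identifiability and state labels

Estimation fixes the reference class to the first state in estimation order;
reporting reorders states by ascending emission mean (labels L/M/H for
M = 3), permuting every coefficient block and carrying the reference index
along, which leaves all probabilities unchanged.  The reported estimates we
ship (`sathmm.reference`) are stored in ascending-mean order with the
*medium* state as reference, matching how the source study presented them —
its software default reference (the first estimated class) turned out to be
the medium class.  The two conventions are interchangeable; a test asserts
the invariance.

### Accumulation window

The accumulated covariates at item j are, by default, means over items
1..j ("inclusive"), which is the literal reading of how the source analysis
defined them; note this lets item j's own outcome inform the transition
*into* item j.  A "lagged" mode (means over 1..j−1) is available wherever
designs are built, for leakage-safe analyses.  The generator always uses the
lagged window: a generative transition into item j can only condition on
history before j.  We do not claim either window is what the original
analysis used — both are implemented.

## Estimation

EM with a scaled forward–backward E-step run vectorized across participants;
per-item transition matrices come from the logit blocks evaluated at each
participant × item design row.  Numerical protections: per-item
max-subtraction of the emission log-densities plus per-step normalization
(underflow-free by construction), an emission SD floor of 1e-3 on the y
scale (constant choice sequences otherwise drive an SD to zero — in the real
data roughly one in nine performance-condition participants never changed
level), and a ridge of 1e-6 on slope (not intercept) rows of the inner
multinomial fits to survive quasi-separation at extreme covariate values.

M-step: emission means/SDs are gamma-weighted pooled moments; the
initial-state block is a weighted multinomial-logistic fit of the item-1
posteriors on the initial design; each origin state's transition block is a
weighted multinomial-logistic fit of the xi slabs on the transition design
(one regression per origin state).  The weighted multinomial solver is
in-house (L-BFGS on the weighted multinomial deviance with analytic
gradient, warm-started from the previous outer iteration; intercept-only
designs use the closed-form normalized-count MLE).  Tests cross-check it
against scikit-learn's multinomial logistic regression on row-expanded data.

Initialization is deterministic: emission means at the (m−0.5)/M quantiles
of pooled y, SDs at the pooled SD, logit coefficients zero.  Restarts jitter
the means with seed-controlled N(0, 0.05) noise and the best log-likelihood
wins.  Convergence: |Δloglik|/(1+|loglik|) < 1e-8, at most 500 outer
iterations.  EM ascent (monotone trace up to 1e-8 relative) is asserted in
tests.  Viterbi decoding runs in log space with the time-varying matrices;
ties break toward the lower state index.

## Model ladder and comparison

Six rungs: A (M=2, no covariates), B (M=3), B1 (initial covariates), B2a
(B1 + condition-driven transitions), B2b (B1 + confidence/correctness-driven
transitions), B3 (all transition covariates).  Parameter count:
2M + (1+q_I)(M−1) + (1+q_h)M(M−1), which reproduces the reported df column
(7, 14, 20, 26, 38, 62).  AIC = −2ℓ + 2k; BIC = −2ℓ + k·ln(n) with
n = participants × items — the only sample-size convention that reproduces
the reported BIC values from the reported log-likelihoods, a derivation kept
as a test.  Nested rungs are compared by LRT with the naive chi-square
reference; regularity conditions for such tests in latent Markov models are
asserted, not proven, which is a known caveat.

## Effect summaries

`sathmm.effects` evaluates the fitted logit blocks on covariate grids:
initial-state probabilities over d × p, transition matrices over
d × f × r, with each transition row aggregated into stay/upward/downward
masses.  The "extreme quadrant" evaluations use f, r ∈ {0, 1} exactly; the
source figures describe the quadrants verbally ("all incorrect"/"all
correct", lowest/highest confidence) without printing the evaluation points,
so this is the assumption under which the reported percentages (66.1%,
22.3%, 27.7%, 73.8%) are recomputed — they land within the rounding of the
published two-decimal coefficients.  The reported high-state downward figure
is read as the *total* downward mass (to M plus to L); the per-destination
probabilities are also available in the tidy output.  Output is numeric
tables, not stacked-bar graphics.

## Descriptives

Choice distributions, strict up/down manifest-transition counts, exact-match
frequent-sequence tables, and pooled point-biserial/Pearson correlations are
straightforward.  For the lag structure, the source analysis residualized
choices with a generalized additive mixed model before computing
autocorrelations; this package instead uses two-way fixed-effects demeaning
(subtract participant and item means, add the grand mean) — simpler,
deterministic, and free of smoothing choices.  Average lag-1 autocorrelations
from the two residualizations are not numerically interchangeable; the
package's ACF is validated against injected AR(1) structure instead.
Participants with constant sequences (or numerically constant residuals) are
excluded from the ACF average with a warning.

## Synthetic cohort generator

Defaults mirror the study conditions: 583 participants × 40 items, balanced
Bernoulli(0.5) condition assignment, pre-test scores truncated-normal
(mean 0.75, SD 0.16, support [0.22, 1]), and 3-state generating parameters
equal to the reported intercept-only estimates: μ = (0.19, 0.51, 0.86),
σ = (0.07, 0.12, 0.13), π = (0.36, 0.45, 0.19), transition rows
(0.93, 0.05, 0.02)/(0.04, 0.92, 0.04)/(0.04, 0.06, 0.90).  Covariate slopes
in the generating parameters are supported (used in tests of LRT power).

Per item: the latent state is drawn from the initial or transition logit
model (lagged covariates); a continuous preference is drawn from the state's
Gaussian, rounded to the nearest level and clamped to 1..7; correctness is
Bernoulli with the chosen level's success probability (0.92, 0.80, 0.68,
0.55, 0.41, 0.30, 0.16 for levels 1–7), shifted on the logit scale by
`ability_slope · (pretest − 0.75)` (default slope 1.0, a modest ±0.3-logit
swing across the pre-test range, so that pre-test score means something for
performance; set 0 to disable); confidence is
`clip(round10(0.33 + 0.37·correct + N(0, 0.24)))`.  The confidence constants
are calibrated so the pooled confidence–correctness point-biserial
correlation is ≈ 0.60, the value observed in the real data; the linear-
Gaussian form itself is an artifact choice — the study offers no generative
account of confidence.  Correctness depends on the chosen level and pre-test
only, not on the latent state directly, mirroring the study design where
difficulty determines success probability.

What the generator reproduces: the scaled mixture structure of choices
(pooled distribution matching the discretized Gaussian mixture within
sampling error, modes at levels 1 and 4), state persistence, the negative
difficulty–correctness and difficulty–confidence associations (emergent from
the monotone success table), r_pb(confidence, correctness) ≈ 0.60, ~92%
correct at level 1, >85% Viterbi recovery of true states (≈98% at the
default separations), and discretization bias below 0.01 on each state mean.

What it does not reproduce: exactly constant manifest sequences are far
rarer than in the real data (a Gaussian emission with σ ≈ 0.07–0.13 almost
surely wobbles across level boundaries within 40 items, whereas 11.5% of
real performance-condition participants never changed level), so the
frequent-sequence table of a default synthetic cohort is flatter than the
real one; real-data quantities that depend on idiosyncratic behavior (the
22.85% level-1 share, the −0.30/−0.28 correlations, the ≈0.44 lag-1 residual
autocorrelation) are context, not targets.  Passing tests on synthetic data
therefore validate the machinery and the recoverability of the generating
structure, not distributional fidelity to the unavailable raw data.

## Problem sizes and tolerances used in validation

Parameter-recovery checks run at the full study size (583 × 40): emission
means within ±0.02 after ascending relabeling, intercept-only transition
diagonals within ±0.03.  Brute-force oracles (path enumeration for the
forward pass and Viterbi) run at M ≤ 3, T ≤ 6 with 1e-9 agreement.  LRT
power and model-selection checks use smaller cohorts (200 × 30 and 80 × 15)
with capped EM iterations, sizes chosen to keep the full suite fast while
leaving the checks decisive.  Effect-surface recomputations from the
published coefficient blocks are asserted to 0.5 percentage points, the
scale of error induced by the blocks' two-decimal rounding.

## Known limitations

- No standard errors or confidence intervals on coefficients (none were
  reported for the source estimates either); no bootstrap or
  cross-validated likelihoods.
- M is configurable but untested beyond 4 states; no higher-order or
  continuous-time chains, no multivariate emissions.
- The inclusive accumulation window leaks item j's outcome into the
  transition into item j; use the lagged window when that matters.
- The LRT chi-square reference and the continuous treatment of a 7-point
  scale are both conventional approximations, inherited knowingly.
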