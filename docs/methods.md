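# Methods

## Task structure emulated by the generator

A session is 6 forced trials (one arm open; 3 per arm in shuffled order,
so both contingencies are sampled) followed by 16 free trials (both arms
open; the measured decisions).  Subjects run 10 sessions, so a full cohort
contributes 160 free trials per subject.  The arm that carries the
reported option sits left or right according to a pseudo-random schedule:
each session's side is drawn uniformly unless the side has been constant
for two consecutive sessions, in which case it is reversed — no side ever
persists longer than two sessions.  Free trials are omitted (no choice
recorded) with a per-experiment rate (defaults 0.80% / 0.02% / 0.13%);
omitted trials are excluded from all analyses.  Forced trials never enter
choice fractions.

One note on counts: the session is described in places as 21 trials, but
its stated composition (6 forced + 16 free) totals 22; the composition is
what the analyses require (160 free trials/subject), so the generator uses
22 trials per session.

The generator has two choice mechanisms. *Fixed-rate* mode draws every
free choice iid Bernoulli(p) toward the reported option — the regime of
the simulated theory predictions (p = 0.6 toward a predicted-preferred
option, 0.4 toward a predicted-non-preferred one, the weakest choice
strengths considered clearly off-chance).  *Agent* mode computes each
arm's utility under a value theory and draws choices through a softmax;
`hierarchical_rates` additionally draws per-subject rates from the group
beta model for calibration studies.  A single numpy `Generator`, seeded
from the cohort spec, drives all draws, so identical specs give
byte-identical tables.

What the generator does **not** emulate: within-session learning,
relearning of reversed contingencies, side biases, or sequential
dependence between trials.  Passing tests therefore demonstrate
correctness of the inference machinery under the analysis model's own
assumptions (exchangeable Bernoulli choices), not robustness to the
learning dynamics visible in real data.

## Value theories

No equations for the three theories are fixed by the underlying study;
the functional forms here are this package's choices, kept as simple as
the qualitative hypotheses allow and swappable via
`value_models.UTILITY_FUNCTIONS`:

- **Aversive discounting**: `U = R·d(t_r; k_r) − S·d(t_s; k_s)` with the
  hyperbolic factor `d(t; k) = 1/(1 + kt)` for both the reward value R and
  the shock cost S (hyperbolic decline of aversive value mirrors temporal
  reward discounting).
- **Utility from anticipation**: the above minus `dread·S·t_s` — dread
  linear in shock magnitude and entry-to-shock delay, the simplest form
  that grows monotonically with the wait.  An anticipation integral or
  exponential form would serve equally; only monotonicity drives the
  qualitative predictions.
- **Spill-over devaluation**: the reward term is scaled by
  `1 − m·exp(−λ·(t_r − t_s))`, exponential decay of the devaluation in the
  shock-to-reward interval.  The form assumes the shock precedes the
  reward, true of every design here.

Choices follow a logistic softmax `p(a) = 1/(1+exp(−τ(U_a − U_b)))`;
τ = 0 is random choice.  Utilities are in arbitrary units; only
differences matter.  Ties within 1e-9 are reported as "indifferent".

Documented reference regions (`value_models.REFERENCE_PARAMS`): the two
classic theories use k_r = k_s = 0.1 s⁻¹, R = S = 1, dread = 0.5 for the
anticipation theory.  The spill-over region sets k_r = k_s = 0 with
m = 0.5, λ = 0.15 s⁻¹, which isolates the spill-over mechanism: the shock
terms then cancel within every design, so experiment 2 (equal
shock-to-reward intervals) is *exactly* indifferent, experiment 1 prefers
EL and experiment 3 prefers EL over EE — the observed pattern.

## Hierarchical Bernoulli–beta model

See README for the model statement.  The beta is mode-parameterized:
shapes `a = μ(κ−2)+1`, `b = (1−μ)(κ−2)+1` are ≥ 1 for every admissible
(μ, κ), so the subject-level prior is never U-shaped, and κ = 2 is the
uniform floor.  The diffuse Gamma(0.01, 0.01) (shape–rate; mean 1) sits on
κ − 2, keeping every prior draw inside the support.

### Sampler

Adaptive Metropolis-within-Gibbs on the unconstrained scales
(logit μ, log(κ−2), logit θ_s):

1. θ-block: given (μ, κ) the θ_s are conditionally independent, so all
   subjects are proposed and accepted element-wise in one vectorized
   Gaussian random-walk step (the per-subject log target collapses to
   `(k+a)·log θ + (n−k+b)·log(1−θ)` once the logit Jacobian is folded in);
2. scalar random-walk updates of logit μ and log(κ−2) against the summed
   beta log-density of the current θ's plus hyperpriors.

Proposal scales adapt per coordinate toward 0.44 acceptance in batches of
50 during warmup only (Robbins–Monro step min(0.1, b^−1/2)), leaving the
post-warmup kernel fixed.  Chains initialize at jittered smoothed
empirical rates; per-chain RNG streams are spawned from the run seed.
Clamping μ and/or κ (delta prior) is supported; with both clamped each θ_s
posterior is the conjugate Beta(a+k, b+n−k), which serves as the analytic
oracle in the tests (the marginal (μ, κ) posterior is also available in
collapsed beta-binomial form and is used as a grid-integration cross-check
in development, never as the sampler).

### Summaries and diagnostics

- **HDI**: narrowest window of ⌈0.95·N⌉ sorted draws; on multimodal draw
  sets the single shortest interval is returned and a warning logged.
- **R̂**: classic split-half Gelman–Rubin (rank-free); a single trending
  chain is caught by the split.  Constant chains give NaN.
- **ESS**: chain-averaged FFT autocorrelations, summed with Geyer's
  initial-monotone positive-sequence truncation; constant chains give 0.
- Convergence gate: summaries refuse (or warn under `force`) when the
  group-level R̂ ≥ 1.05; the pipeline default demands ESS > 1,000 for μ
  at full chain settings.

### Problem sizes

The reference MCMC setting is 12 chains × 15,000 iterations (5,000
warmup).  The pipeline default is 4 chains × 5,000 iterations (1,000
warmup), which puts the Monte-Carlo error of the μ HDI bounds below 0.003
for cohort-sized data — an order of magnitude under the parameter's
posterior spread — while keeping a full fit under ~2 s.  The calibration
study uses 2 chains × 1,500 per replicate for the same reason at 200
replicates.  Calibration cohorts are drawn from the model itself at
μ = 0.55 and κ = 22 (between-subject SD ≈ 0.10, moderate heterogeneity;
κ = 22 gives the convenient integer shapes 12, 10), then fit with the full
prior; coverage of μ's 95% HDI is checked against its nominal rate.

### A note on the simulated-prediction interval width

For a 25-subject × 160-trial fixed-rate cohort the model's 95% HDI for μ
has width ≈ 0.041 (confirmed by exact grid integration of the collapsed
posterior): the hierarchical layer adds between-subject uncertainty on
top of the pooled binomial width (≈ 0.030).  A complete-pooling analysis
of the same data would give the narrower interval; the package reports
the hierarchical one, consistent with the model as stated.

## Frequentist battery

One-sample two-tailed t-tests compare per-subject percent choices of the
reported arm against the 50% chance level.  Two blockings feed the
repeated-measures ANOVAs: trial blocks (free trials 1–8 vs 9–16 within
each session, crossed with session 1–10) and session blocks (sessions 1–5
vs 6–10, crossed with order within block).  "Trials 1–8" counts free-trial
serial position, since only free trials carry decisions.  The ANOVA is the
classical fully-within two-way decomposition; each effect is tested
against its own subject-by-effect stratum; effect size is partial
η² = SS_eff/(SS_eff+SS_err).  For factors with ≥ 3 levels Mauchly's test
(α = 0.05) decides whether Greenhouse–Geisser corrected degrees of freedom
are reported alongside the uncorrected ones.  Subjects with an empty cell
are dropped listwise with a warning and the error dfs shrink accordingly.
The SS decomposition is implemented directly (and cross-checked against
pingouin in the tests); sphericity and ε delegate to pingouin.

## Degenerate inputs and numerical choices

- Subjects with zero valid free trials yield an explicit missing fraction
  (None), never a silent 0, and are excluded from group tests.
- Zero-variance samples and n < 2 are rejected by the t-test; ANOVA
  effects whose SS is numerically null (< 1e-12 of SS_total) report F = 0
  rather than 0/0 noise.
- The softmax saturates without overflow; log-densities return −∞ outside
  support; κ exactly at the floor is outside the point-density support
  (the gamma density diverges there).
- All tolerances used in tests are stated next to the assertion they
  guard; Monte-Carlo assertions use 3-SE binomial bands.

## Known limitations

- The sampler is a random-walk scheme: for very large κ the θ-block mixes
  slowly relative to gradient-based samplers; the diagnostics (R̂, ESS)
  guard the summaries.
- The three utility functions are illustrative parameterizations of the
  verbal theories, adequate for direction-of-preference predictions, not
  for fitting (no fitting is performed).
- Agent-mode cohorts hold the choice probability constant across trials;
  no learning or session effects are generated, so the ANOVAs on
  synthetic data exercise machinery, not behavior.
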