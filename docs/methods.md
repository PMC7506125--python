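# Methods

## Models

All four models are Rescorla–Wagner learners over per-stimulus action
values Q with a softmax choice rule,

    P(a(t) = i) = exp(β·Q_i(t)) / Σ_j exp(β·Q_j(t)),

where β ∈ [0, 10] is the inverse temperature and the sum runs over the
stimuli offered on that trial. Only the chosen (or forced) stimulus's
value is updated. By default the learning rate carries a decaying bonus

    α′ = α + 0.5 / (1 + T_s),

where T_s counts the trials on which stimulus s's outcome has been
experienced (forced exposures included). The bonus makes early estimates
behave like running sample means and decays to the base rate α ∈ [0, 1].
A `decay=False` flag gives the constant-rate variant, used for the
simple bandit simulations; a `clip` flag caps α′ at 1 (off by default,
so the raw formula is used even when α > 0.5 makes early α′ exceed 1).

* **qlearning** — `Q ← Q + α′(r − Q)`.
* **utility** — the delta rule tracks a subjective utility with anchors
  U(0) = 0, U(20) = 20, U(40) = a·20 (task units of cents; a ∈ [1, 30];
  a = 2 is the identity). For outcomes off the three-point support the
  anchors are interpolated by the power law U(x) = u·(x/u)^log2(a) with
  u = 20 × reward_scale, odd-extended to negative x. On the discrete
  support the power law coincides exactly with the anchor table, so it
  is the single implementation path.
* **risk_sensitive** — separate learning rates α⁺/α⁻ for positive and
  negative prediction errors. At exactly zero prediction error the
  increment is zero whichever rate is used, so no tie rule is needed.
* **surprise** — the surprise-sensitive utility model. The outcome's
  subjective value is reduced in proportion to the surprise (absolute
  prediction error), S = r − d·|r − Q|, with d ∈ [−1, 1], and the delta
  rule tracks S. d = 0 recovers plain Q-learning bit-for-bit; d > 0
  devalues surprising outcomes of either valence.

Action values start at `q0 = 0` by default (configurable). Exact nested
identities (surprise d=0, risk-sensitive α⁺=α⁻, utility a=2 all equal
Q-learning trajectories to the last bit) are enforced by tests.

## Tasks

* **risk234** — the risky, probabilistic learning task: five slot
  machines (sure 40c, sure 20c, two sure 0c, and a risky machine paying
  0c or 40c with equal probability) over 234 trials in three 78-trial
  sessions. Composition: 30 risk trials {20 vs risky}; 20 each of the
  test pairs {40 vs risky}, {20 vs 40}, {0 vs risky}, {0 vs 20}; forced
  exposures 24/24/24 for the 40/20/risky machines and 16 for each 0c
  machine; and 20 {0 vs 0} trials. Trial order is one seeded uniform
  permutation of all 234 templates cut into three consecutive blocks
  (no within-session balancing), and the agent's state persists across
  blocks. The two 0c machines are distinct stimuli with separate Q and
  T_s; the {0 vs risky} and {0 vs 20} test pairs use the first of them.
* **bandit2** — an all-choice two-armed Bernoulli bandit (default
  reward probabilities 0.8/0.2, magnitude 1, 500 trials).
* **gauss4** — a four-armed bandit whose arms share a mean payoff of
  €250 but differ in outcome sd (0/10/30/70), 200 trials; draws are not
  truncated at zero.

Each task carries a multiplicative `reward_scale`. β and the reward
scale trade off inside the softmax, so a fitted β is only interpretable
together with the scale, and the scale is recorded in every artifact.

## Simulation experiments and their conditions

Simulated conditions that the underlying studies leave unstated are
fixed here once, as follows.

* **risk-sweep** (risk aversion vs d): surprise-model agents on
  risk234, d ∈ {0, 0.25, 0.5, 0.75, 1} × α ∈ {0.2, 0.5, 0.8}, β = 2 on
  reward_scale = 0.05 (outcomes 0/1/2 in units of 20 cents — β = 2 at
  this scale equals β = 0.1 on cents, a realistic sensitivity), 1000
  agents per cell, each with a freshly permuted trial order. Action
  values start at the mean offered payoff (16 cents scaled to 0.8)
  rather than 0: with a pessimistic all-zero start, the surprise update
  S − Q = (1 − d)(r − Q) vanishes identically at d = 1 for non-negative
  outcomes, the agent provably learns nothing, and choice collapses to
  uniform — the growth of risk aversion over the full d range requires
  a non-degenerate prior expectation. The outcome measure is the
  fraction of the 30 {sure 20 vs risky} trials on which the sure option
  was taken. Risk aversion rises monotonically in d for every α, and
  the d = 0 → 1 rise is larger at α = 0.8 than at α = 0.2 (≈ +0.025,
  stable across seeds at 1000 agents/cell).
* **stay-compare / stay-dsweep** (reward-history signature): 0.8/0.2
  Bernoulli bandit, 500 trials, constant learning rate, α = 0.3, β = 2;
  surprise model d = 0.5 (or d ∈ {0.1, 0.5, 0.9}); 1000 agents. Stay
  probability at trial t is P(a(t+1) = a(t)), stratified only by the
  reward history (r(t−1) > 0, r(t) > 0) — no requirement that the same
  arm was chosen at t−1 and t. The surprise model stays less than
  Q-learning after rewarded trials, most strongly after a surprising
  reward (r(t−1) = 0, r(t) = 1), and the rewarded-condition stay
  probability falls as d grows.
* **safe-options**: two arms, both p = 0.9, magnitudes 1 vs 0.8 (small
  gap) or 1 vs 0.3 (large gap); α = 0.3, d = 0.5. The two model
  contrasts occupy different choice regimes and are run in both. Near
  value equilibrium (β = 2, 500 trials) surprise rescales both arms'
  values by the same factor c(d) < 1 (for an arm paying r with
  probability p, Q* = pr(1−d) / (p(1−d) + (1−p)(1+d)) = c·r), which
  always shrinks the softmax gap: the surprise model picks the better
  arm *less* often than Q-learning, visibly at the small gap. Under
  decisive, short-horizon choice (β = 10, 50 trials) the low-value arm
  stays under-sampled, its value far from equilibrium, and the few
  visits it gets are punished hardest by surprise: at the large gap the
  surprise model picks the better arm *more* often than Q-learning. A
  systematic search (β 2–10, α 0.1–0.5, horizon 20–1000, several
  initializations) found no single parameter setting where both
  directions hold at once; this regime dependence is a property of the
  model, and the experiment reports the full 2 × 2 × 2 table.

Standard errors in all summaries are between-agent (between-subject).

## Fitting

Per-subject maximum a posteriori estimation. Priors: Beta(2, 2) on all
learning rates (support [0, 1]); Gamma(shape 2, scale 3) on β (mode 3,
support box [0, 10]; a `gamma_rate` switch reads the second
hyperparameter as a rate instead, since the (2, 3) notation is
ambiguous); Uniform(1, 30) on the utility curvature a; Uniform(−1, 1)
on the surprise decay d (deliberately allowing negative d so its sign
is a finding, not an assumption). Densities are not renormalized for
the box truncation — the constants are shared across models for shared
parameters and do not move the MAP.

The likelihood replays the session in order: choice trials contribute
the log softmax probability of the recorded choice, forced trials
contribute nothing, and every trial updates the state with the recorded
reward. Optimization is box-constrained L-BFGS-B from `n_restarts = 10`
start points drawn from the priors (bounds inset by 1e-6 because some
prior densities vanish at the edges); the best optimum is kept and the
whole procedure is deterministic given its seed.

Model evidence is the Laplace approximation at the mode,

    log p(D|M) ≈ log p(D, θ̂|M) + (k/2)·log 2π − ½·log det H,

with H the Hessian of the negative log posterior from central finite
differences (relative step 1e-4 per coordinate, steps shrunk near box
edges so all evaluations stay inside the support). A mode within 1e-4
of a box edge is nudged inward and flagged `boundary`; a non-positive-
definite Hessian is ridged to positive definiteness and flagged
`regularized`. Against brute-force grid quadrature of the posterior on
50-trial two-parameter sessions the approximation is typically within
0.03–0.05 nats; occasional sessions whose mode sits near a box edge can
reach ~0.2 nats. On synthetic Gaussian log posteriors it is exact to
numerical precision.

## Group model selection

Random-effects Bayesian model selection from the subjects × models
matrix of Laplace log evidences: a variational Dirichlet posterior over
population model frequencies (fixed-point iteration on responsibilities
g_nk ∝ exp(l_nk + ψ(α_k) − ψ(Σα)), prior count α₀ = 1, tolerance 1e-6
on max |Δα|), exceedance probabilities by Monte Carlo over the
Dirichlet (10⁶ draws by default, seeded; the exact Beta tail is
available at K = 2), the Bayes omnibus risk

    BOR = 1 / (1 + exp(F1 − F0)),

where F1 is the converged variational free energy (expected log joint
plus entropies minus the Dirichlet KL) and F0 = Σ_n log((1/K)Σ_k
exp(l_nk)) is the exact evidence of the equal-frequency null, and the
protected exceedance probability pxp = (1 − BOR)·xp + BOR/K. With
exactly symmetric evidences F1 < F0 always (the null is favored and
BOR → 1 as subjects accumulate), and pxp is exactly uniform. The
one-sample t-test on fitted parameters is the classical test with
df = n − 1; zero-variance samples return t = 0 (mean equals the null)
or signed infinity (it does not), flagged by a p of 1 or 0.

## Synthetic cohorts

Cohorts stand in for group datasets (e.g. 16 subjects × 234 risk-task
trials, or 163 subjects × 200 Gaussian-bandit trials): per-subject
parameters are drawn from configurable laws — by default uniform over
each parameter's box, except β from its Gamma prior truncated to
[0, 10] so that near-zero-β subjects (whose choices carry no signal) are
rare — and each subject is simulated with a seed spawned from the
master seed by a counter-based scheme, so cohorts are reproducible as a
whole and per subject. Recovery experiments on the risk task use
reward_scale = 0.05 for the same β-scale reason as the sweeps. On 50
surprise-model subjects with d ~ Uniform(0, 1), the correlation between
true and recovered d is ≈ 0.9–0.98 (the tested bound is ≥ 0.7); model
recovery over four 12-subject cohorts identifies the generating model
by highest pxp in at least 3 of 4 conditions (surprise and Q-learning
are confusable when the generating d is small, so the surprise cohort
draws d from [0.5, 1]).

What the cohorts do not emulate: reaction times, missed trials,
within-session non-stationarity, or any participant covariates. Tests
passing on these cohorts show that the estimation and selection
machinery is correct and well-calibrated under the models' own
generative assumptions; they do not show that the models describe real
choice behavior.

## Numerical choices and limitations

* Softmax is computed with max-subtraction; probabilities are exact
  under shifts of all Q values.
* Problem sizes in tests and the acceptance script (1000 agents per
  simulated cell, 50-subject recovery cohorts, 12-subject recovery
  confusion cohorts, 161² quadrature grids, 2×10⁵–10⁶ Dirichlet draws)
  were chosen so the full suite runs in a few minutes while keeping
  Monte-Carlo error well below every asserted margin.
* The Laplace evidence assumes an interior, locally Gaussian mode;
  boundary-flagged fits should be treated with caution.
* The variational free energy bookkeeping follows the standard
  Dirichlet-multinomial form; different implementations of the same
  scheme can differ by small constants, so only its limiting behaviors
  (symmetry, dominance, BOR calibration) are asserted.
* Adapters for particular public datasets' column layouts are out of
  scope; `read_sessions` defines the package's own documented CSV
  dialect.
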