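# Methods

## Task model

The simulator reproduces a two-person two-armed bandit with changing
controllability. Defaults (all overridable through `TaskConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_tasks` × `trials_per_task` | 2 × 100 | two sessions of 100 trials |
| `n_self_blocks` + `n_other_blocks` | 4 + 4 | alternating controller blocks |
| `block_len_min..max` | 20–30 | trials per block |
| `p_reward_optimal` | 0.8 | reward probability of the controller's optimal option |
| `probe_interval_choices` | {2, 3} | trials between probes |

Block lengths are drawn by rejection: i.i.d. uniform integers on
[20, 30] accepted when they sum to the exact trial count, giving a uniform
distribution over reachable compositions. Blocks alternate starting with a
self-controllable block; each block's optimal option is an independent
fair coin, so it can move between self-controllable blocks. Only the
controller's action is compared against the block optimum when the outcome
is drawn; the other agent's choice never enters. Causality probes appear
in the second session, mood probes (structural placeholders, no mood
model) in the first; inter-probe gaps are i.i.d. uniform on the allowed
set, with the first probe after the first gap.

The partner is a Rescorla-Wagner softmax learner (learning rate 0.3,
inverse temperature 1.5, values initialized at 0.5) that chooses and
updates on every trial — it cannot know whether it is currently in
control. Its behavioral identifiability is checked by refitting an RW
model to its simulated choice stream (recovered learning rate within
±0.05 of 0.3 at 5,000 trials).

## Controllability inference model

State: contingency tables p(reward | z, A) for z ∈ {self, other} and
A ∈ {left, right}, initialized at 0.5; a prediction p̂ = p̂(z=1),
initialized at 0.5. All learned state resets at each session boundary
(the two sessions are separate runs; the model is given no carry-over).

Per trial, in order:

1. **Choice.** β = β₀·(p̂/(1−p̂))^τ; V(A) is the self-frame contingency;
   p(right) = logistic(β·(V_r − V_l)).
2. **Learning.** Delta-rule update of the observed (frame, action) cell
   for both frames with rates a_self, a_other. (A mirrored update of the
   unchosen cell to the complement — motivated by the instruction that
   exactly one option is optimal — is available as an off-by-default
   flag; the model equations update only the taken action.)
3. **Likelihoods** from the *updated* tables; a loss has the complement
   likelihood, the unique consistent extension of the reward definition.
4. **Posterior.** p = w·L_s·p̂ / (w·L_s·p̂ + L_o·(1−p̂)) with
   w = exp(bias_pos) after reward, exp(bias_neg) after loss; computed in
   log space and clipped to [1e−6, 1−1e−6]. LCR = log p/(1−p).
5. **Report** (on causality probes): p(report self) =
   logistic(β_con·(2p−1)). The argument is the posterior difference
   p(z=1) − p(z=0); the log-odds form is available via
   `ModelSpec(report_form="lcr")`. The difference form is bounded and
   symmetric around the indifference point.
6. **Drift.** p̂ ← (1−θ)·p + 0.5·θ.

Parameters (natural domains): a_self, a_other, θ ∈ (0,1); β₀, β_con > 0;
bias_pos, bias_neg, τ unconstrained. Limits used as test identities:
τ = 0 freezes β at β₀; θ = 1 pins predictions at 0.5; bias → ±∞ saturates
the posterior at the clip bounds; β = 0 gives coin-flip choices.

Variants are nested restrictions expressed as flags: `mabc_nobias`
(biases 0), `mabc_notau` (τ = 0), `mabc_nodrift` (θ = 0), `single_agent`
(other-likelihood fixed at chance 0.5, so inference uses self evidence
only; a_other becomes inert and is pinned), and `flat` (everything off,
β₀ = β_con = 0: pure chance). With a flag's parameters at their pinned
values the restricted and full code paths agree bit for bit.

An N-agent generalization (`generalized_posterior`) normalizes
w_i·L_i·prior_i with the bias weighting only the self entry; the
two-agent case reduces exactly to the pairwise update.

The sequential recursion is implemented twice on purpose: once as plain
single-step functions (the reference), once as a numba kernel used by
simulation-scale fitting; the test suite asserts trace equality at 1e−10
against a third, independently written brute-force calculator.

## Fitting

MAP estimation in transformed space — logit for (0,1) parameters, log for
positive ones, identity for unconstrained ones — under independent
Gaussian priors, by multi-start L-BFGS-B (default 10 restarts: prior mean
plus unit Gaussian jitter; gradient tolerance 1e−6; box bounds far outside
the priors' mass). The Hessian of the negative log-joint is taken by
central finite differences (relative step 1e−4) and the log model
evidence by Laplace: LME = log-joint(MAP) + (d/2)·log 2π − ½·log|H|. A
non-positive-definite Hessian receives an escalating diagonal ridge
(flagged in the result and warned); models with no free parameters get
LME = log-likelihood exactly. The Laplace machinery is validated against
the closed-form evidence of a conjugate Gaussian-mean problem (1e−6).

**Prior hyperparameters.** The defaults are mean 0, variance 4 in the
estimation space for every parameter — a deliberately weak, symmetric
choice, prominently overridable via `PriorSpec` (e.g.
`PriorSpec.default(variance=1.0)` or per-parameter overrides). These
hyperparameters matter: they define both the shrinkage target of the MAP
and the population sampled by the parameter-recovery experiment (below).

## Model selection

Random-effects BMS: subjects' model identities are multinomial draws with
Dirichlet-distributed frequencies (prior α₀ = 1). The variational fixed
point alternates responsibilities g_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα))
with α = α₀ + Σ_n g_n, to max |Δα| < 1e−6. Exceedance probabilities are
Monte-Carlo (10⁶ Dirichlet draws by default, seeded; for K = 2 the tests
check them against the exact Beta tail). The Bayesian omnibus risk
compares the converged variational free energy F1 (including the
Dirichlet KL term and responsibility entropy) with the equal-frequency
null F0 = Σ_n log(mean_k exp(lme_nk)): BOR = 1/(1+exp(F1−F0));
PEP_k = EP_k·(1−BOR) + BOR/K. Outputs are invariant to per-subject LME
offsets and equivariant under model permutation (tested).

## Recovery experiments and synthetic cohorts

**Parameter recovery** samples subject parameters from the fitting priors
(through the estimation transforms), simulates one default-task session
per subject against the partner, refits, and correlates true with
recovered values in the estimation space, where the sampling distribution
is Gaussian. At N = 200 subjects, seven of the eight parameters recover
with r ≈ 0.25–0.71 (all p < 3e−4). The exception is **a_other**, the
partner-frame learning rate: it expresses itself almost solely through
the ~40 causality probes of a 200-trial session, and prior-sampled
cohorts contain many subjects (near-zero β_con, saturating biases) whose
data carry no other-agent information, so its recovery correlation is
~0.03 under the default priors (~0.12 under unit-variance priors) and is
not significant at this cohort size. A dedicated test shows a_other *is*
identifiable when it alone varies in an otherwise favorable regime
(r ≈ 0.46 at n = 40). This is a power limitation of the desk-scale
experiment, not of the estimator; a cohort orders of magnitude larger, or
a task with probes in both sessions, would be needed to resolve a_other
from prior-wide populations.

**Model recovery** simulates one 20-subject cohort per variant, fits all
variants to every cohort, and records the PEP winner. Cohorts are
generated from a canonical parameter set (a = 0.3, bias_pos = 0.23,
bias_neg = −0.26, β₀ = 2, τ = 0.5, θ = 0.2) with transformed-space
Gaussian scatter (sd 0.25) — values chosen to reproduce the directional
phenomena of interest (positive reward bias, negative loss bias, positive
value utilization) at human-like causality accuracy (~0.56–0.60). The
recovery harness uses reliable reporters (β_con = 6, `STRONG_PARAMS`):
with the weaker canonical β_con = 3 the full and single-agent variants
are *not* separable at 20 subjects — the single-agent model's remaining
parameters absorb most of the ~1 nat per-subject advantage — which is
itself an informative boundary condition on desk-scale model recovery.

**Behavioral signatures** (tested on a 60-subject canonical cohort with
wider bias scatter, sd 0.75): SELF reports increase with the subject's own
action-outcome consistency (CIx_self) and decrease with the partner's
(CIx_other) in a pooled logistic regression; across subjects, bias_pos
correlates positively with the illusion of control and with second-half
optimal choice in self-controllable blocks (partial correlations with a
balanced binary covariate standing in for the sex covariate of the study
design). These are sign checks: the synthetic cohort is not a human
sample, and effect sizes are not comparable.

## What the generator does and does not emulate

The simulator reproduces the task's event statistics (block structure,
contingency, probe cadence) and a behaving partner, so model-level claims
(recovery, selection, signatures) transfer to the task *design*. It does
not emulate human reaction times, mood dynamics (mood probes are
placeholders), session-order effects, or any population structure beyond
independent parameter draws, so passing tests say nothing about fit
quality to real human data.

## Numerical choices

Probabilities are clipped at ε = 1e−6 before logs and odds ratios; the
posterior is computed in log space; softmax arguments with exactly equal
values short-circuit to 0.5 (so infinite β never produces NaN); choice and
report likelihoods are floored at ε inside the log. Equal-value argmax
ties in exceedance sampling go to the first index (measure zero).
Experiment seeds derive from `numpy.random.SeedSequence([seed, ...])`
spawn keys, so batch results are independent of execution order; every
simulation is bit-reproducible from its seed.

## Problem sizes

Default experiment sizes were chosen so the full validation suite runs in
minutes on one core: recovery at 200 subjects × 200 trials (restarts 3),
model recovery at 3 cohorts × 20 subjects × 3 models, signatures at 60
subjects, Monte-Carlo EP at 10⁵–10⁶ draws. All sizes are arguments.
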