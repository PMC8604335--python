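"""Multi-agent Bayesian controllability (MABC) model family.

An agent shares a two-armed bandit with a partner; only one of them controls
the outcome at any time (latent state z, z=1 "I am in control"). The agent
learns reward contingencies p(reward | action) separately for its own and
the partner's actions by delta-rule updates, turns them into likelihoods of
the observed outcome under each controller hypothesis, and combines the two
with the prior prediction in a Bayes step. Valence-dependent biases
(``bias_pos`` after reward, ``bias_neg`` after loss) multiply the
self-likelihood by ``exp(bias)``; the posterior is then pulled toward 0.5 by
a drift ``theta`` to form the next trial's prediction. Predicted
controllability also scales the softmax inverse temperature of the
outcome-related choice, beta = beta0 * (p_hat/(1-p_hat))**tau — the
"value utilization" channel. Causality reports arise from a logistic read-out
of the posterior with inverse temperature ``beta_con``.

The single-step operations here are plain Python and serve as the reference
implementation; :func:`session_loglik` delegates the whole-session loop to a
compiled kernel that the tests check against these steps.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import task as task_mod
from ._core import EPS, mabc_session_loglik
from .task import SessionLog, TaskConfig, TrialRecord, run_session

PARAM_NAMES = ("a_self", "a_other", "bias_pos", "bias_neg",
               "beta0", "tau", "theta", "beta_con")


def _clip(p: float) -> float:
    return float(min(max(p, EPS), 1.0 - EPS))


@dataclass(frozen=True)
class MABCParams:
    """Subject-level parameters of the full model.

    a_self, a_other : contingency learning rates, in (0,1)
    bias_pos, bias_neg : log-scale self-likelihood weights after reward/loss
    beta0 : baseline softmax inverse temperature, > 0
    tau : controllability modulation exponent on the inverse temperature
    theta : drift of the prediction toward 0.5, in (0,1)
    beta_con : inverse temperature of the causality report, > 0
    """

    a_self: float = 0.3
    a_other: float = 0.3
    bias_pos: float = 0.0
    bias_neg: float = 0.0
    beta0: float = 2.0
    tau: float = 0.0
    theta: float = 0.1
    beta_con: float = 3.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "MABCParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))

    def replace(self, **kw) -> "MABCParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ModelSpec:
    """A variant of the model family, expressed as feature flags.

    Switching a flag off pins the corresponding parameters (see
    ``fixed_values``), so every variant is a nested restriction of the full
    model. ``report_form`` selects the argument of the causality-report
    logistic: the posterior difference 2p-1 (default) or the log odds.
    """

    label: str
    use_other_likelihood: bool = True
    use_bias: bool = True
    use_tau: bool = True
    use_drift: bool = True
    fixed: dict = field(default_factory=dict)
    report_form: str = "difference"  # or "lcr"
    mirror_update: bool = False

    def __post_init__(self):
        if self.report_form not in ("difference", "lcr"):
            raise ValueError(f"unknown report_form {self.report_form!r}")

    @property
    def fixed_values(self) -> dict:
        out = dict(self.fixed)
        if not self.use_bias:
            out.setdefault("bias_pos", 0.0)
            out.setdefault("bias_neg", 0.0)
        if not self.use_tau:
            out.setdefault("tau", 0.0)
        if not self.use_drift:
            out.setdefault("theta", 0.0)
        if not self.use_other_likelihood:
            # other-likelihood is replaced by chance, so a_other is inert
            out.setdefault("a_other", 0.3)
        return out

    @property
    def free_params(self) -> tuple[str, ...]:
        fixed = self.fixed_values
        return tuple(p for p in PARAM_NAMES if p not in fixed)

    def pin(self, params: MABCParams) -> MABCParams:
        """Overwrite pinned parameters with their fixed values."""
        return params.replace(**self.fixed_values)


MODEL_SPECS: dict[str, ModelSpec] = {
    "mabc_full": ModelSpec("mabc_full"),
    "mabc_nobias": ModelSpec("mabc_nobias", use_bias=False),
    "mabc_notau": ModelSpec("mabc_notau", use_tau=False),
    "mabc_nodrift": ModelSpec("mabc_nodrift", use_drift=False),
    "single_agent": ModelSpec("single_agent", use_other_likelihood=False),
    "flat": ModelSpec("flat", use_other_likelihood=False, use_bias=False,
                      use_tau=False, use_drift=False,
                      fixed={"beta0": 0.0, "beta_con": 0.0,
                             "a_self": 0.3, "a_other": 0.3}),
}


def get_spec(label: str) -> ModelSpec:
    try:
        return MODEL_SPECS[label]
    except KeyError:
        raise KeyError(f"unknown model label {label!r}; "
                       f"known: {sorted(MODEL_SPECS)}") from None


@dataclass
class ContingencyTable:
    """Learned p(reward | controller hypothesis, action).

    Row index is the controller frame (1 = self, 0 = other), column index
    the action (0 = left, 1 = right). Starts uninformative at 0.5.
    """

    p_reward: np.ndarray = field(
        default_factory=lambda: np.full((2, 2), 0.5))

    def copy(self) -> "ContingencyTable":
        return ContingencyTable(self.p_reward.copy())


def update_contingency(table: ContingencyTable, agent_frame: int, action: int,
                       outcome: int, rate: float) -> ContingencyTable:
    """Delta-rule update of the observed (frame, action) cell only."""
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    out = table.copy()
    p = out.p_reward[agent_frame, action]
    out.p_reward[agent_frame, action] = p + rate * (outcome - p)
    return out


def compute_likelihoods(table: ContingencyTable, action_self: int,
                        action_other: int, outcome: int) -> tuple[float, float]:
    """Outcome likelihood under the self- and other-controller hypotheses.

    Contingencies store p(reward | .); a loss likelihood is the complement.
    Uses the table as handed in — callers apply the current trial's
    contingency update first, matching the event order of the task.
    """
    ps = table.p_reward[1, action_self]
    po = table.p_reward[0, action_other]
    if outcome == 1:
        return float(ps), float(po)
    return float(1.0 - ps), float(1.0 - po)


def posterior_update(prior_pred_self: float, likelihood_self: float,
                     likelihood_other: float, outcome: int,
                     params: MABCParams,
                     spec: Optional[ModelSpec] = None) -> float:
    """Valence-biased Bayes step for p(z=1 | actions, outcome)."""
    spec = spec or MODEL_SPECS["mabc_full"]
    for v in (prior_pred_self, likelihood_self, likelihood_other):
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite belief input {v!r}")
    pp = _clip(prior_pred_self)
    lo = 0.5 if not spec.use_other_likelihood else likelihood_other
    bias = 0.0
    if spec.use_bias:
        bias = params.bias_pos if outcome == 1 else params.bias_neg
    log_num = bias + np.log(max(likelihood_self, EPS)) + np.log(pp)
    log_alt = np.log(max(lo, EPS)) + np.log(1.0 - pp)
    return _clip(float(expit(log_num - log_alt)))


def predict_next(posterior_self: float, theta: float) -> float:
    """Drift the inferred controllability toward 0.5 for the next trial."""
    return (1.0 - theta) * posterior_self + 0.5 * theta


def action_values(table: ContingencyTable) -> tuple[float, float]:
    """The self-frame contingencies double as action values (V_left, V_right)."""
    return float(table.p_reward[1, 0]), float(table.p_reward[1, 1])


def trial_inverse_temperature(prior_pred_self: float, params: MABCParams,
                              spec: Optional[ModelSpec] = None) -> float:
    """beta = beta0 * (p_hat / (1 - p_hat)) ** tau."""
    spec = spec or MODEL_SPECS["mabc_full"]
    if not spec.use_tau:
        return params.beta0
    pp = _clip(prior_pred_self)
    return float(params.beta0 * np.exp(params.tau * np.log(pp / (1.0 - pp))))


def choice_prob(v_left: float, v_right: float, beta_trial: float) -> float:
    """Logistic choice rule: p(choose RIGHT)."""
    d = v_right - v_left
    if d == 0.0:
        return 0.5
    return float(expit(beta_trial * d))


def causality_report_prob(posterior_self: float, beta_con: float,
                          form: str = "difference") -> float:
    """p(report SELF): logistic of the posterior difference (or log odds)."""
    p = _clip(posterior_self)
    if form == "difference":
        x = beta_con * (2.0 * p - 1.0)
    elif form == "lcr":
        x = beta_con * np.log(p / (1.0 - p))
    else:
        raise ValueError(f"unknown report form {form!r}")
    return float(1.0 / (1.0 + np.exp(-x)))


def lcr(posterior_self: float) -> float:
    """Log-controllability ratio log p(z=1)/p(z=0)."""
    p = _clip(posterior_self)
    return float(np.log(p / (1.0 - p)))


def generalized_posterior(prior_vector, likelihood_vector, bias_pos: float = 0.0,
                          bias_neg: float = 0.0, outcome: int = 1) -> np.ndarray:
    """N-agent Bayes step: entry 0 is self, the rest are other agents.

    The valence bias weighs only the self entry (w_self = exp(bias),
    w_other = 1); with two agents this reduces exactly to
    :func:`posterior_update`.
    """
    prior = np.asarray(prior_vector, dtype=float)
    lik = np.asarray(likelihood_vector, dtype=float)
    if prior.shape != lik.shape:
        raise ValueError("prior and likelihood vectors must have equal length")
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must sum to 1")
    bias = bias_pos if outcome == 1 else bias_neg
    w = np.ones_like(prior)
    w[0] = np.exp(bias)
    post = w * lik * prior
    return post / post.sum()


@dataclass
class BeliefTrace:
    """Per-trial internal variables of one model evaluation."""

    prior_pred_self: np.ndarray
    likelihood_self: np.ndarray
    likelihood_other: np.ndarray
    posterior_self: np.ndarray
    lcr: np.ndarray
    value_left: np.ndarray
    value_right: np.ndarray
    beta_trial: np.ndarray
    p_choose_right: np.ndarray
    p_report_self: np.ndarray  # NaN on trials without a causality probe

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f.name: getattr(self, f.name)
                             for f in dataclasses.fields(self)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def session_arrays(session: SessionLog) -> dict[str, np.ndarray]:
    """Flatten a session log into the arrays the compiled kernel consumes."""
    recs = session.records
    n = len(recs)
    out = {
        "actions_self": np.array([r.action_self for r in recs], dtype=np.int64),
        "actions_other": np.array([r.action_other for r in recs], dtype=np.int64),
        "outcomes": np.array([r.outcome for r in recs], dtype=np.int64),
        "is_causality": np.array([r.probe == "CAUSALITY" for r in recs]),
        "probe_resp": np.array(
            [{"SELF": 1, "OTHER": 0}.get(r.probe_response, -1)
             if r.probe == "CAUSALITY" else -1 for r in recs], dtype=np.int64),
        "task_start": np.zeros(n, dtype=np.bool_),
    }
    task_ids = np.array([r.task_id for r in recs])
    out["task_start"][0] = True
    out["task_start"][1:] = task_ids[1:] != task_ids[:-1]
    return out


def session_loglik(session: SessionLog, params: MABCParams,
                   spec: ModelSpec | str = "mabc_full") -> tuple[float, BeliefTrace]:
    """Joint log-likelihood of all choices and causality reports.

    Per trial: choice likelihood from the prediction-modulated softmax,
    delta-rule contingency updates from the recorded actions and outcome,
    likelihoods from the *updated* table, biased posterior, report
    likelihood on causality probes, then the drifted prediction for the
    next trial. Learning state resets at each task boundary.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    p = spec.pin(params)
    arrs = session_arrays(session)
    res = mabc_session_loglik(
        arrs["actions_self"], arrs["actions_other"], arrs["outcomes"],
        arrs["is_causality"], arrs["probe_resp"], arrs["task_start"],
        p.a_self, p.a_other, p.bias_pos, p.bias_neg, p.beta0, p.tau,
        p.theta, p.beta_con,
        spec.use_other_likelihood, spec.report_form == "lcr",
        spec.mirror_update)
    ll, *trace = res
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite session log-likelihood: {ll}")
    return float(ll), BeliefTrace(*trace)


class MABCPolicy:
    """Generative subject: acts and answers probes from its own beliefs.

    Maintains the model recursion incrementally as trial records stream in,
    using the reference single-step operations, so simulated behavior and
    the fitted likelihood describe exactly the same process.
    """

    def __init__(self, params: MABCParams, spec: ModelSpec | str = "mabc_full",
                 rng: Optional[np.random.Generator] = None,
                 trials_per_task: int = 100):
        if isinstance(spec, str):
            spec = get_spec(spec)
        self.spec = spec
        self.params = spec.pin(params)
        self.rng = rng or np.random.default_rng()
        self.trials_per_task = trials_per_task
        self._reset_beliefs()
        self._seen = 0
        self._task = None
        self.posterior = 0.5

    def _reset_beliefs(self):
        self.table = ContingencyTable()
        self.prior_pred = 0.5

    def _consume(self, history: Sequence[TrialRecord]) -> None:
        for rec in history[self._seen:]:
            if rec.task_id != self._task:
                self._reset_beliefs()
                self._task = rec.task_id
            self.table = update_contingency(
                self.table, 1, rec.action_self, rec.outcome, self.params.a_self)
            self.table = update_contingency(
                self.table, 0, rec.action_other, rec.outcome, self.params.a_other)
            ls, lo = compute_likelihoods(
                self.table, rec.action_self, rec.action_other, rec.outcome)
            self.posterior = posterior_update(
                self.prior_pred, ls, lo, rec.outcome, self.params, self.spec)
            self.prior_pred = predict_next(self.posterior, self.params.theta)
        self._seen = len(history)

    def act(self, history: Sequence[TrialRecord]) -> int:
        self._consume(history)
        # the first action of a new task must come from fresh beliefs, before
        # any record of that task exists; _consume's own reset (idempotent)
        # fires once the record arrives
        upcoming_task = len(history) // self.trials_per_task + 1
        if upcoming_task != self._task:
            self._reset_beliefs()
        beta = trial_inverse_temperature(self.prior_pred, self.params, self.spec)
        vl, vr = action_values(self.table)
        p_right = choice_prob(vl, vr, beta)
        return int(self.rng.random() < p_right)

    def probe_answer(self, history: Sequence[TrialRecord]) -> int:
        self._consume(history)
        p = causality_report_prob(self.posterior, self.params.beta_con,
                                  self.spec.report_form)
        return int(self.rng.random() < p)


def simulate_subject(config: TaskConfig, params: MABCParams,
                     spec: ModelSpec | str = "mabc_full",
                     seed: int = 0,
                     partner_params: Optional[dict] = None) -> SessionLog:
    """Closed-loop generative run: MABC subject vs the RW partner."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    ss = np.random.SeedSequence([seed, 7])
    policy = MABCPolicy(params, spec, np.random.default_rng(ss),
                        trials_per_task=config.trials_per_task)
    log = run_session(config, policy, partner_params=partner_params,
                      rng_seed=seed)
    log.generator_params = {"params": spec.pin(params), "spec": spec.label}
    return log
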