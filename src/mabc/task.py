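"""Two-person changing-controllability bandit task.

Simulates the paradigm in which two agents each pick one of two options on
every trial but only one of them — the current *controller* — actually
determines the shared outcome. The controller flips between the subject
("SELF") and an artificial partner ("OTHER") every 20–30 trials; within a
controller's own blocks one option is optimal (rewarded with probability
``p_reward_optimal``), the other suboptimal. The partner is a
Rescorla-Wagner softmax learner. Causality probes ("who caused that
outcome?") are interleaved every 2–3 trials in the second task session;
the first session carries mood probes, recorded here as placeholders.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
import yaml

SELF = "SELF"
OTHER = "OTHER"
LEFT = 0
RIGHT = 1

_ACTION_LABEL = {0: "LEFT", 1: "RIGHT"}
_ACTION_CODE = {"LEFT": 0, "RIGHT": 1}
_PROBE_VOCAB = {"NONE", "CAUSALITY", "MOOD"}
_RESPONSE_VOCAB = {"SELF", "OTHER", "NA"}

CSV_COLUMNS = [
    "trial", "task_id", "true_controller", "action_self", "action_other",
    "outcome", "probe", "probe_response",
]


class TaskConfigError(ValueError):
    """Raised for infeasible or invalid task configurations."""


class ProtocolError(RuntimeError):
    """Raised when a subject policy violates the task protocol."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the two-session task.

    Defaults reproduce the study design: 2 sessions x 100 trials, 4
    self-controllable and 4 other-controllable blocks of 20-30 trials,
    80/20 reward contingency for the controller, probes every 2-3 trials.
    """

    n_tasks: int = 2
    trials_per_task: int = 100
    block_len_min: int = 20
    block_len_max: int = 30
    n_self_blocks: int = 4
    n_other_blocks: int = 4
    p_reward_optimal: float = 0.8
    probe_interval_choices: tuple[int, ...] = (2, 3)
    first_block_self: bool = True
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        n_blocks = self.n_self_blocks + self.n_other_blocks
        if not (0.0 < self.p_reward_optimal < 1.0):
            raise TaskConfigError(
                f"p_reward_optimal must lie in (0,1), got {self.p_reward_optimal}")
        if self.block_len_min > self.block_len_max or self.block_len_min < 1:
            raise TaskConfigError("invalid block length range")
        total = self.n_trials
        if not (n_blocks * self.block_len_min <= total <= n_blocks * self.block_len_max):
            raise TaskConfigError(
                f"{n_blocks} blocks of length [{self.block_len_min}, "
                f"{self.block_len_max}] cannot sum to {total} trials")
        if abs(self.n_self_blocks - self.n_other_blocks) > 1:
            raise TaskConfigError("alternating blocks require counts differing by at most 1")
        if not self.probe_interval_choices or min(self.probe_interval_choices) < 1:
            raise TaskConfigError("probe intervals must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_tasks * self.trials_per_task

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "probe_interval_choices" in raw:
            raw["probe_interval_choices"] = tuple(raw["probe_interval_choices"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["probe_interval_choices"] = list(self.probe_interval_choices)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class ControllabilitySchedule:
    """Per-trial controller assignment and optimal-option layout.

    ``controller`` is 1 where the subject controls the outcome, 0 where the
    partner does. ``controller_optimal`` gives, for every trial, the option
    that is optimal *for whoever controls that trial*; ``subject_optimal``
    is the subject-frame view (-1, i.e. NONE, in other-controllable blocks,
    where no option is optimal for the subject).
    """

    controller: np.ndarray
    controller_optimal: Optional[np.ndarray]
    subject_optimal: Optional[np.ndarray]
    block_boundaries: np.ndarray
    p_reward_optimal: float = 0.8

    def __len__(self) -> int:
        return len(self.controller)


def generate_schedule(config: TaskConfig, rng: np.random.Generator) -> ControllabilitySchedule:
    """Draw a controllability schedule.

    Block lengths are sampled by rejection: i.i.d. uniform integers in
    ``[block_len_min, block_len_max]``, accepted once they sum to the exact
    trial count, which is uniform over the reachable compositions.
    Controllers alternate between blocks; each block's optimal option is an
    independent fair draw, so it may differ between self-controllable blocks.
    """
    n_blocks = config.n_self_blocks + config.n_other_blocks
    total = config.n_trials
    lo, hi = config.block_len_min, config.block_len_max
    if lo == hi:
        lengths = np.full(n_blocks, lo)
    else:
        for _ in range(100_000):
            lengths = rng.integers(lo, hi + 1, size=n_blocks)
            if lengths.sum() == total:
                break
        else:  # pragma: no cover - astronomically unlikely for feasible configs
            raise TaskConfigError("block-length rejection sampler failed to accept")

    first = 1 if config.first_block_self else 0
    block_ctrl = [(first + i) % 2 for i in range(n_blocks)]
    if sum(block_ctrl) != config.n_self_blocks:
        raise TaskConfigError(
            "alternation starting with "
            f"{'SELF' if config.first_block_self else 'OTHER'} cannot yield "
            f"{config.n_self_blocks} self blocks out of {n_blocks}")

    controller = np.empty(total, dtype=np.int8)
    controller_optimal = np.empty(total, dtype=np.int8)
    boundaries = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    pos = 0
    for ctrl, length in zip(block_ctrl, lengths):
        opt = int(rng.integers(2))
        controller[pos:pos + length] = ctrl
        controller_optimal[pos:pos + length] = opt
        pos += length
    subject_optimal = np.where(controller == 1, controller_optimal, -1).astype(np.int8)
    return ControllabilitySchedule(
        controller=controller,
        controller_optimal=controller_optimal,
        subject_optimal=subject_optimal,
        block_boundaries=boundaries,
        p_reward_optimal=config.p_reward_optimal,
    )


def draw_outcome(schedule: ControllabilitySchedule, trial: int,
                 action_controller: int, rng: np.random.Generator) -> int:
    """Sample the shared outcome: only the controller's action matters."""
    if schedule.controller_optimal is None:
        raise ValueError("schedule carries no optimal-option layout")
    p = (schedule.p_reward_optimal
         if action_controller == schedule.controller_optimal[trial]
         else 1.0 - schedule.p_reward_optimal)
    return int(rng.random() < p)


@dataclass
class PartnerAgent:
    """Rescorla-Wagner softmax learner standing in for the second player.

    Learns p(reward | own action) with a fixed learning rate and picks
    actions through a logistic policy on the value difference; it acts and
    updates on every trial since it cannot know who is in control.
    """

    learning_rate: float = 0.3
    inv_temp: float = 1.5
    q_values: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def p_right(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.inv_temp * (self.q_values[1] - self.q_values[0]))))

    def step(self, rng: np.random.Generator) -> int:
        return int(rng.random() < self.p_right())

    def update(self, action: int, outcome: int) -> None:
        self.q_values[action] += self.learning_rate * (outcome - self.q_values[action])


@dataclass
class TrialRecord:
    trial: int            # 0-based internally; written 1-based to disk
    task_id: int
    true_controller: str  # SELF | OTHER
    action_self: int      # 0=LEFT, 1=RIGHT
    action_other: int
    outcome: int          # 1=reward, 0=loss
    probe: str = "NONE"   # NONE | CAUSALITY | MOOD
    probe_response: str = "NA"  # SELF | OTHER | NA


class SubjectPolicy(Protocol):
    """What the session loop needs from a subject: actions and probe answers.

    ``act`` is called before the current trial completes (history holds all
    finished trials); ``probe_answer`` is called after the outcome, with the
    just-finished trial included in the history. Stateful policies may
    ignore the history and track the stream incrementally.
    """

    def act(self, history: Sequence[TrialRecord]) -> int: ...

    def probe_answer(self, history: Sequence[TrialRecord]) -> int:
        """Return 1 to report SELF, 0 to report OTHER."""
        ...


class RandomPolicy:
    """Coin-flip subject: uninformative baseline for task-level statistics."""

    def __init__(self, rng: np.random.Generator, p_right: float = 0.5,
                 p_report_self: float = 0.5):
        self.rng = rng
        self.p_right = p_right
        self.p_report_self = p_report_self

    def act(self, history) -> int:
        return int(self.rng.random() < self.p_right)

    def probe_answer(self, history) -> int:
        return int(self.rng.random() < self.p_report_self)


@dataclass
class SessionLog:
    """Complete record of one simulated two-session run."""

    records: list[TrialRecord]
    schedule: ControllabilitySchedule
    config: Optional[TaskConfig]
    generator_params: Optional[dict] = None
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "trial": r.trial + 1,
            "task_id": r.task_id,
            "true_controller": r.true_controller,
            "action_self": _ACTION_LABEL[r.action_self],
            "action_other": _ACTION_LABEL[r.action_other],
            "outcome": r.outcome,
            "probe": r.probe,
            "probe_response": r.probe_response,
        } for r in self.records]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   config: Optional[TaskConfig] = None) -> "SessionLog":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trial log missing columns: {missing}")
        trials = frame["trial"].to_numpy()
        if not np.all(np.diff(trials) == 1) or trials[0] != 1:
            raise ValueError("trial index must be 1-based and strictly consecutive")
        records = []
        for row in frame.itertuples(index=False):
            if row.true_controller not in (SELF, OTHER):
                raise ValueError(f"bad controller label {row.true_controller!r}")
            if row.action_self not in _ACTION_CODE or row.action_other not in _ACTION_CODE:
                raise ValueError("actions must be LEFT or RIGHT")
            if row.probe not in _PROBE_VOCAB or row.probe_response not in _RESPONSE_VOCAB:
                raise ValueError("bad probe vocabulary")
            if int(row.outcome) not in (0, 1):
                raise ValueError("outcome must be 0 (loss) or 1 (reward)")
            records.append(TrialRecord(
                trial=int(row.trial) - 1,
                task_id=int(row.task_id),
                true_controller=row.true_controller,
                action_self=_ACTION_CODE[row.action_self],
                action_other=_ACTION_CODE[row.action_other],
                outcome=int(row.outcome),
                probe=row.probe,
                probe_response=row.probe_response,
            ))
        controller = np.array(
            [1 if r.true_controller == SELF else 0 for r in records], dtype=np.int8)
        switches = np.flatnonzero(np.diff(controller) != 0) + 1
        schedule = ControllabilitySchedule(
            controller=controller,
            controller_optimal=None,
            subject_optimal=None,
            block_boundaries=np.concatenate([[0], switches]),
            p_reward_optimal=config.p_reward_optimal if config else 0.8,
        )
        return cls(records=records, schedule=schedule, config=config)

    @classmethod
    def read_csv(cls, path, config: Optional[TaskConfig] = None) -> "SessionLog":
        # keep_default_na: the literal token NA is part of the vocabulary
        return cls.from_frame(pd.read_csv(path, keep_default_na=False),
                              config=config)


def _probe_positions(n_trials: int, choices: Sequence[int],
                     rng: np.random.Generator) -> list[int]:
    # gaps i.i.d. uniform over the allowed intervals; first probe after the
    # first gap (e.g. gap 2 -> probe on the 2nd trial of the task)
    choices = np.asarray(choices)
    positions, pos = [], -1
    while True:
        pos += int(rng.choice(choices))
        if pos >= n_trials:
            return positions
        positions.append(pos)


def run_session(config: TaskConfig, subject_policy: SubjectPolicy,
                partner_params: Optional[dict] = None,
                rng_seed: int = 0) -> SessionLog:
    """Simulate a full run: subject vs RW partner on the generated schedule.

    All randomness inside the loop derives from ``rng_seed`` (the policy's
    own generator, if any, is the caller's responsibility), so the log is
    bit-for-bit reproducible.
    """
    ss = np.random.SeedSequence(rng_seed)
    sched_rng, outcome_rng, partner_rng, probe_rng = (
        np.random.default_rng(c) for c in ss.spawn(4))
    schedule = generate_schedule(config, sched_rng)
    partner = PartnerAgent(**(partner_params or {}))

    probe_type: dict[int, str] = {}
    for task in range(config.n_tasks):
        kind = "CAUSALITY" if (task + 1) == 2 else "MOOD"
        for p in _probe_positions(config.trials_per_task, config.probe_interval_choices, probe_rng):
            probe_type[task * config.trials_per_task + p] = kind

    records: list[TrialRecord] = []
    for t in range(config.n_trials):
        task_id = t // config.trials_per_task + 1
        a_self = subject_policy.act(records)
        if a_self not in (0, 1):
            raise ProtocolError(f"policy returned invalid action {a_self!r} at trial {t}")
        a_other = partner.step(partner_rng)
        ctrl = int(schedule.controller[t])
        a_ctrl = a_self if ctrl == 1 else a_other
        outcome = draw_outcome(schedule, t, a_ctrl, outcome_rng)
        partner.update(a_other, outcome)

        rec = TrialRecord(
            trial=t, task_id=task_id,
            true_controller=SELF if ctrl == 1 else OTHER,
            action_self=a_self, action_other=a_other, outcome=outcome,
            probe=probe_type.get(t, "NONE"),
        )
        records.append(rec)
        if rec.probe == "CAUSALITY":
            ans = subject_policy.probe_answer(records)
            if ans not in (0, 1):
                raise ProtocolError(
                    f"policy returned invalid probe answer {ans!r} at trial {t}")
            rec.probe_response = SELF if ans == 1 else OTHER

    return SessionLog(records=records, schedule=schedule, config=config,
                      seed=rng_seed)


def simulate_partner_trials(n_trials: int, learning_rate: float = 0.3,
                            inv_temp: float = 1.5, p_reward_optimal: float = 0.8,
                            block_len: tuple[int, int] = (20, 30),
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Run the RW partner alone as permanent controller of the bandit.

    The optimal side is redrawn at block switches (uniform 20-30 trial
    blocks), as in its own controllable blocks of the main task. Returns
    the partner's actions and the outcomes — the raw material for checking
    that an RW model refit to this stream recovers the generating
    parameters.
    """
    rng = np.random.default_rng(seed)
    agent = PartnerAgent(learning_rate=learning_rate, inv_temp=inv_temp)
    actions = np.empty(n_trials, dtype=np.int64)
    outcomes = np.empty(n_trials, dtype=np.int64)
    remaining, optimal = 0, 0
    for t in range(n_trials):
        if remaining == 0:
            remaining = int(rng.integers(block_len[0], block_len[1] + 1))
            optimal = int(rng.integers(2))
        a = agent.step(rng)
        o = int(rng.random() < (p_reward_optimal if a == optimal else 1 - p_reward_optimal))
        agent.update(a, o)
        actions[t], outcomes[t] = a, o
        remaining -= 1
    return actions, outcomes
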