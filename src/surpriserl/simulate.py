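"""Agent simulation and behavioral summary statistics.

Runs model agents through a task and computes the summaries used to
characterize behavior: the probability of choosing the sure option on
risk trials, stay probability stratified by reward history, and per-arm
choice rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import AgentState, ModelParams, _choice_probs, update_state
from .tasks import TaskSpec, sample_outcome


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial: what was offered, what was chosen, what it paid."""

    index: int  # 1-based
    trial_type: str
    offered: Tuple[str, ...]
    choice: str
    reward: float

    def __post_init__(self) -> None:
        if self.choice not in self.offered:
            raise ValueError(f"trial {self.index}: choice {self.choice!r} not among offered")
        if self.trial_type == "forced" and len(self.offered) != 1:
            raise ValueError(f"trial {self.index}: forced trial must offer exactly one stimulus")


@dataclass
class SessionData:
    """Ordered trial records for one subject on one task."""

    subject_id: str
    task: TaskSpec
    trials: List[TrialRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = set(self.task.stimulus_ids)
        for i, tr in enumerate(self.trials, start=1):
            if tr.index != i:
                raise ValueError(f"trial index gap at row {i}: got {tr.index}")
            unknown = set(tr.offered) - ids
            if unknown:
                raise ValueError(f"trial {i}: unknown stimuli {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def choice_trials(self) -> List[TrialRecord]:
        return [t for t in self.trials if t.trial_type == "choice"]


def simulate_agent(
    params: ModelParams,
    task: TaskSpec,
    seed,
    *,
    q0: float = 0.0,
    decay: bool = True,
    clip: bool = False,
    subject_id: str = "sim",
) -> SessionData:
    """Run one agent through the task, sampling choices and outcomes.

    Choice trials sample from the softmax over offered Q values; forced
    trials deliver the single offered stimulus. The state update and the
    outcome draw happen on every trial. Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    state = AgentState.initial(task.stimulus_ids, q0=q0)
    unit = 20.0 * task.reward_scale
    stim_by_id = {s.id: s for s in task.stimuli}
    records: List[TrialRecord] = []
    for i, tpl in enumerate(task.trials, start=1):
        if tpl.trial_type == "choice":
            probs = _choice_probs([state.Q[s] for s in tpl.offered], params.beta)
            u = rng.random()
            acc = 0.0
            choice = tpl.offered[-1]
            for sid, p in zip(tpl.offered, probs):
                acc += p
                if u < acc:
                    choice = sid
                    break
        else:
            choice = tpl.offered[0]
        reward = sample_outcome(stim_by_id[choice], rng, task.reward_scale)
        state = update_state(
            state, params, choice, reward,
            decay=decay, clip=clip, utility_unit=unit, inplace=True,
        )
        records.append(TrialRecord(i, tpl.trial_type, tpl.offered, choice, reward))
    return SessionData(subject_id=subject_id, task=task, trials=records)


@dataclass(frozen=True)
class SureChoiceSummary:
    per_subject: np.ndarray
    mean: float
    sem: float


def prob_sure_choice(
    sessions: Sequence[SessionData],
    sure_id: str = "sure20",
    risky_id: str = "risky",
) -> SureChoiceSummary:
    """Per-subject fraction of {sure vs risky} choice trials on which the sure option won.

    These are the "risk" trials of the risky probabilistic learning task;
    the grand mean is the behavioral index of risk aversion.
    """
    target = frozenset((sure_id, risky_id))
    per_subject = []
    for sess in sessions:
        qualifying = [
            t for t in sess.choice_trials() if frozenset(t.offered) == target
        ]
        if not qualifying:
            raise ValueError(
                f"session {sess.subject_id!r} has no {{{sure_id} vs {risky_id}}} choice trials"
            )
        per_subject.append(np.mean([t.choice == sure_id for t in qualifying]))
    values = np.asarray(per_subject, dtype=float)
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return SureChoiceSummary(per_subject=values, mean=float(values.mean()), sem=sem)


#: stay-probability condition labels, ordered (r(t-1), r(t))
STAY_CONDITIONS = (
    ("r(t-1)=0", "r(t)=0"),
    ("r(t-1)=0", "r(t)=1"),
    ("r(t-1)=1", "r(t)=0"),
    ("r(t-1)=1", "r(t)=1"),
)


def stay_probability_table(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Stay probability by reward history (r(t-1), r(t)).

    For each trial t with both a predecessor and a successor, the trial
    is classified by whether the previous and current outcomes were
    rewarded (strictly positive), and a "stay" is choosing the same arm
    at t+1 as at t. Conditioning uses reward history only (no requirement
    that the same arm was chosen at t-1 and t). Rows are per-condition
    means with between-subject standard errors.
    """
    per_agent: Dict[Tuple[bool, bool], List[float]] = {
        (False, False): [], (False, True): [], (True, False): [], (True, True): []
    }
    counts = {k: 0 for k in per_agent}
    for sess in sessions:
        if sess.n_trials < 3:
            raise ValueError("stay probability needs at least 3 trials")
        if any(t.trial_type != "choice" for t in sess.trials):
            raise ValueError("stay probability is defined for all-choice-trial bandits")
        rewards = [t.reward for t in sess.trials]
        choices = [t.choice for t in sess.trials]
        stays: Dict[Tuple[bool, bool], List[bool]] = {k: [] for k in per_agent}
        for t in range(1, sess.n_trials - 1):
            cond = (rewards[t - 1] > 0, rewards[t] > 0)
            stays[cond].append(choices[t + 1] == choices[t])
            counts[cond] += 1
        for cond, events in stays.items():
            if events:
                per_agent[cond].append(float(np.mean(events)))
    rows = []
    for cond_key, (lab_prev, lab_curr) in zip(
        ((False, False), (False, True), (True, False), (True, True)), STAY_CONDITIONS
    ):
        vals = np.asarray(per_agent[cond_key], dtype=float)
        rows.append(
            {
                "prev_rewarded": int(cond_key[0]),
                "curr_rewarded": int(cond_key[1]),
                "label": f"{lab_prev}, {lab_curr}",
                "stay_prob": float(vals.mean()) if len(vals) else float("nan"),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "n_agents": len(vals),
                "n_events": counts[cond_key],
            }
        )
    return pd.DataFrame(rows).set_index("label")


def choice_rate(sessions: Sequence[SessionData], stimulus: str) -> float:
    """Mean over agents of the fraction of offering choice trials that picked ``stimulus``."""
    per_agent = []
    for sess in sessions:
        offering = [t for t in sess.choice_trials() if stimulus in t.offered]
        if offering:
            per_agent.append(np.mean([t.choice == stimulus for t in offering]))
    if not per_agent:
        raise ValueError(f"stimulus {stimulus!r} was never offered on a choice trial")
    return float(np.mean(per_agent))
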