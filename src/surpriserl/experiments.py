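"""Named simulation experiments and their default conditions.

These bundles fix the study conditions used throughout the package:

* ``risk-sweep`` — surprise-model agents on the 234-trial risky task,
  sweeping the surprise decay rate d over {0, 0.25, 0.5, 0.75, 1} for
  each learning rate alpha in {0.2, 0.5, 0.8}; outcome: mean probability
  of the sure choice on the 30 {sure 20 vs risky 0/40} trials. Risk
  aversion should grow with d, more steeply at high alpha.
* ``stay-compare`` — Q-learning vs the surprise model (alpha=0.3,
  beta=2, d=0.5) on the 0.8/0.2 Bernoulli bandit; outcome: the stay
  probability split by reward history. The surprise model stays less
  after rewarded trials, most markedly after a surprising reward
  (r(t-1)=0, r(t)=1).
* ``stay-dsweep`` — the same bandit with d in {0.1, 0.5, 0.9}.
* ``safe-options`` — two p=0.9 arms differing in magnitude (1 vs 0.8,
  and 1 vs 0.3); outcome: the better arm's choice rate for each model,
  in two choice regimes. The surprise model picks the better arm less
  often than Q-learning at the small gap (long-horizon regime) but more
  often at the large gap (short-horizon decisive regime); the two
  effects do not coexist at a single parameter setting (see
  ``safe_options``).

The risky task's monetary outcomes are expressed in units of 20 cents
(reward_scale = 0.05, payoffs 0/1/2) so that beta = 2 sits sensibly
inside its [0, 10] box; the bandit simulations use the plain 0/1 payoffs
and a constant learning rate. In the risk sweep, action values start at
the mean offered payoff (16 cents): with a pessimistic all-zero start
the surprise model's update S - Q = (1-d)(r-Q) vanishes identically at
d = 1 (nothing is ever learned and choice stays uniform), so risk
aversion could not grow over the whole d range.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import ModelParams
from .simulate import (
    SessionData,
    choice_rate,
    prob_sure_choice,
    simulate_agent,
    stay_probability_table,
)
from .tasks import build_bernoulli_bandit, build_risk_task

#: risky-task simulation conditions (d and alpha are swept)
RISK_SWEEP_BETA = 2.0
RISK_REWARD_SCALE = 0.05
RISK_Q0 = 16.0 * RISK_REWARD_SCALE  # mean offered payoff: (40+20+20+0+0)/5 cents
RISK_D_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
RISK_ALPHA_GRID = (0.2, 0.5, 0.8)

#: two-armed bandit conditions
BANDIT_ALPHA = 0.3
BANDIT_BETA = 2.0
BANDIT_D = 0.5
BANDIT_P = (0.8, 0.2)
BANDIT_N_TRIALS = 500
STAY_D_GRID = (0.1, 0.5, 0.9)


def simulate_many(
    params: ModelParams,
    task_builder,
    n_agents: int,
    seed: int,
    *,
    decay: bool = True,
    clip: bool = False,
    q0: float = 0.0,
    per_agent_task: bool = False,
) -> List[SessionData]:
    """Simulate ``n_agents`` independent agents under one parameter setting.

    With ``per_agent_task`` each agent gets a freshly ordered task (a new
    seeded trial permutation), matching repeated runs of a randomly
    intermixed task.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_agents)
    sessions = []
    task = None if per_agent_task else task_builder(0)
    for i, child in enumerate(children):
        t = task_builder(int(child.generate_state(1)[0] % (2**31))) if per_agent_task else task
        sessions.append(
            simulate_agent(
                params, t, child, decay=decay, clip=clip, q0=q0,
                subject_id=f"S{i + 1:04d}",
            )
        )
    return sessions


def risk_sweep(
    n_agents: int = 1000,
    seed: int = 0,
    d_grid: Sequence[float] = RISK_D_GRID,
    alpha_grid: Sequence[float] = RISK_ALPHA_GRID,
    beta: float = RISK_SWEEP_BETA,
) -> pd.DataFrame:
    """Mean sure-choice probability over the d x alpha grid."""
    rows = []
    for cell, (alpha, d) in enumerate(
        [(a, d) for a in alpha_grid for d in d_grid]
    ):
        params = ModelParams("surprise", alpha=alpha, beta=beta, d=d)
        builder = lambda s: build_risk_task(seed=s, reward_scale=RISK_REWARD_SCALE)
        sessions = simulate_many(
            params, builder, n_agents, seed=seed * 1000 + cell,
            q0=RISK_Q0, per_agent_task=True,
        )
        summary = prob_sure_choice(sessions)
        rows.append({"alpha": alpha, "d": d, "p_sure": summary.mean,
                     "sem": summary.sem, "n_agents": n_agents})
    return pd.DataFrame(rows)


def _bandit_builder(p: Tuple[float, float], r: Tuple[float, float], n_trials: int):
    task = build_bernoulli_bandit(p, r, n_trials)
    return lambda s: task


def stay_compare(
    n_agents: int = 1000,
    seed: int = 0,
    n_trials: int = BANDIT_N_TRIALS,
) -> pd.DataFrame:
    """Stay-probability tables for Q-learning vs the surprise model."""
    builder = _bandit_builder(BANDIT_P, (1.0, 1.0), n_trials)
    frames = []
    for offset, (label, params) in enumerate(
        [
            ("qlearning", ModelParams("qlearning", alpha=BANDIT_ALPHA, beta=BANDIT_BETA)),
            ("surprise", ModelParams("surprise", alpha=BANDIT_ALPHA, beta=BANDIT_BETA, d=BANDIT_D)),
        ]
    ):
        sessions = simulate_many(params, builder, n_agents, seed=seed * 100 + offset, decay=False)
        table = stay_probability_table(sessions).reset_index()
        table.insert(0, "model", label)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def stay_dsweep(
    n_agents: int = 1000,
    seed: int = 0,
    d_grid: Sequence[float] = STAY_D_GRID,
    n_trials: int = BANDIT_N_TRIALS,
) -> pd.DataFrame:
    """Stay-probability tables for the surprise model across d values."""
    builder = _bandit_builder(BANDIT_P, (1.0, 1.0), n_trials)
    frames = []
    for offset, d in enumerate(d_grid):
        params = ModelParams("surprise", alpha=BANDIT_ALPHA, beta=BANDIT_BETA, d=d)
        sessions = simulate_many(params, builder, n_agents, seed=seed * 100 + offset, decay=False)
        table = stay_probability_table(sessions).reset_index()
        table.insert(0, "d", d)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


#: the two choice regimes of the safe-option comparison
SAFE_REGIMES = {
    # long-horizon stochastic choice: values near equilibrium
    "equilibrium": {"beta": 2.0, "n_trials": 500},
    # short-horizon decisive choice: the low-value arm stays under-sampled
    "decisive": {"beta": 10.0, "n_trials": 50},
}


def safe_options(
    n_agents: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Better-arm choice rates on the two safe-option bandits, per regime.

    Both arms reward with p = 0.9; the arms differ only in magnitude
    (small gap: 1 vs 0.8; large gap: 1 vs 0.3). ``arm1`` is the better
    arm. The two model differences live in different choice regimes: in
    the long-horizon "equilibrium" regime, surprise shrinks both arms'
    values proportionally, so the surprise model picks the better arm
    less often than Q-learning (most visibly at the small gap); in the
    short-horizon "decisive" regime the low-value arm stays
    under-sampled and surprise punishes it hardest, so at the large gap
    the surprise model picks the better arm more often than Q-learning.
    """
    rows = []
    for regime, cfg in SAFE_REGIMES.items():
        for gap_label, r2 in (("small_gap", 0.8), ("large_gap", 0.3)):
            builder = _bandit_builder((0.9, 0.9), (1.0, r2), cfg["n_trials"])
            for offset, (label, params) in enumerate(
                [
                    ("qlearning", ModelParams("qlearning", alpha=BANDIT_ALPHA, beta=cfg["beta"])),
                    ("surprise", ModelParams("surprise", alpha=BANDIT_ALPHA, beta=cfg["beta"], d=BANDIT_D)),
                ]
            ):
                sessions = simulate_many(
                    params, builder, n_agents,
                    seed=seed * 1000 + (17 if gap_label == "large_gap" else 0)
                    + (29 if regime == "decisive" else 0) + offset,
                    decay=False,
                )
                rows.append({
                    "regime": regime, "beta": cfg["beta"], "n_trials": cfg["n_trials"],
                    "condition": gap_label, "alt_reward": r2, "model": label,
                    "better_arm_rate": choice_rate(sessions, "arm1"),
                    "n_agents": n_agents,
                })
    return pd.DataFrame(rows)


def run_experiment(name: str, n_agents: int = 1000, seed: int = 0) -> pd.DataFrame:
    if name == "risk-sweep":
        return risk_sweep(n_agents=n_agents, seed=seed)
    if name == "stay-compare":
        return stay_compare(n_agents=n_agents, seed=seed)
    if name == "stay-dsweep":
        return stay_dsweep(n_agents=n_agents, seed=seed)
    if name == "safe-options":
        return safe_options(n_agents=n_agents, seed=seed)
    raise ValueError(f"unknown experiment {name!r}")
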