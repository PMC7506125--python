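"""Task environments: the risky probabilistic learning task and bandits.

Three environments are provided:

* a 234-trial risky, probabilistic learning task mixing forced and choice
  trials over five slot-machine stimuli (sure 40c, sure 20c, two sure 0c,
  and a risky 0-or-40c machine),
* an all-choice Bernoulli multi-armed bandit,
* an all-choice Gaussian multi-armed bandit (equal means, unequal
  outcome variability).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus and its payoff distribution (in task units).

    ``kind`` is one of ``fixed`` (degenerate at ``value``), ``mixture``
    (discrete over ``values`` with ``probs``), or ``gaussian``
    (Normal(``mean``, ``sd``)).
    """

    id: str
    kind: str
    value: float = 0.0
    values: Tuple[float, ...] = ()
    probs: Tuple[float, ...] = ()
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "mixture", "gaussian"):
            raise ValueError(f"unknown payoff kind {self.kind!r}")
        if self.kind == "mixture":
            if len(self.values) != len(self.probs) or not self.values:
                raise ValueError("mixture needs matching non-empty values/probs")
            if abs(sum(self.probs) - 1.0) > 1e-9 or any(p < 0 for p in self.probs):
                raise ValueError("mixture probabilities must be non-negative and sum to 1")
        if self.kind == "gaussian" and self.sd < 0:
            raise ValueError("sd must be non-negative")

    def expected_value(self) -> float:
        if self.kind == "fixed":
            return self.value
        if self.kind == "mixture":
            return float(sum(v * p for v, p in zip(self.values, self.probs)))
        return self.mean

    def to_dict(self) -> dict:
        d = {"id": self.id, "kind": self.kind}
        if self.kind == "fixed":
            d["value"] = self.value
        elif self.kind == "mixture":
            d["values"] = list(self.values)
            d["probs"] = list(self.probs)
        else:
            d["mean"] = self.mean
            d["sd"] = self.sd
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        for k in ("values", "probs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class TrialTemplate:
    """One trial slot: a forced exposure (one stimulus) or a choice (>=2)."""

    trial_type: str
    offered: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.trial_type not in ("choice", "forced"):
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.trial_type == "forced" and len(self.offered) != 1:
            raise ValueError("forced trials offer exactly one stimulus")
        if self.trial_type == "choice" and len(self.offered) < 2:
            raise ValueError("choice trials offer at least two stimuli")


@dataclass(frozen=True)
class TaskSpec:
    """A full task: stimuli, an ordered trial list, and session blocking."""

    stimuli: Tuple[StimulusSpec, ...]
    trials: Tuple[TrialTemplate, ...]
    n_sessions: int = 1
    reward_scale: float = 1.0

    def __post_init__(self) -> None:
        ids = {s.id for s in self.stimuli}
        if len(ids) != len(self.stimuli):
            raise ValueError("duplicate stimulus ids")
        for i, t in enumerate(self.trials):
            missing = set(t.offered) - ids
            if missing:
                raise ValueError(f"trial {i + 1} offers unknown stimuli {sorted(missing)}")
        if self.n_sessions < 1 or (self.trials and len(self.trials) % self.n_sessions):
            raise ValueError("trial count must divide into the declared session blocks")

    @property
    def stimulus_ids(self) -> Tuple[str, ...]:
        return tuple(s.id for s in self.stimuli)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def stimulus(self, stimulus_id: str) -> StimulusSpec:
        for s in self.stimuli:
            if s.id == stimulus_id:
                return s
        raise KeyError(f"unknown stimulus {stimulus_id!r}")

    def to_dict(self) -> dict:
        return {
            "stimuli": [s.to_dict() for s in self.stimuli],
            "trials": [{"trial_type": t.trial_type, "offered": list(t.offered)} for t in self.trials],
            "n_sessions": self.n_sessions,
            "reward_scale": self.reward_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        return cls(
            stimuli=tuple(StimulusSpec.from_dict(s) for s in d["stimuli"]),
            trials=tuple(
                TrialTemplate(t["trial_type"], tuple(t["offered"])) for t in d["trials"]
            ),
            n_sessions=int(d.get("n_sessions", 1)),
            reward_scale=float(d.get("reward_scale", 1.0)),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "TaskSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# canonical stimulus ids of the risky probabilistic learning task
RISK_STIMULI = ("sure40", "sure20", "zero_a", "zero_b", "risky")


def build_risk_task(seed: int = 0, reward_scale: float = 1.0) -> TaskSpec:
    """The 234-trial risky, probabilistic learning task.

    Composition: 30 "risk" choice trials (sure 20 vs risky 0/40); 20 test
    choice trials for each of {40 vs risky}, {20 vs 40}, {0 vs risky},
    {0 vs 20}; 24 forced trials each for the 40, 20 and risky stimuli and
    16 each for the two 0 stimuli; plus 20 {0 vs 0} choice trials. The
    risky machine pays 0 or 40 with equal probability. Trial order is a
    seeded uniform permutation cut into three 78-trial sessions; only the
    order varies with the seed.
    """
    stimuli = (
        StimulusSpec("sure40", "fixed", value=40.0),
        StimulusSpec("sure20", "fixed", value=20.0),
        StimulusSpec("zero_a", "fixed", value=0.0),
        StimulusSpec("zero_b", "fixed", value=0.0),
        StimulusSpec("risky", "mixture", values=(0.0, 40.0), probs=(0.5, 0.5)),
    )
    templates: List[TrialTemplate] = []
    templates += [TrialTemplate("choice", ("sure20", "risky"))] * 30
    for pair in (("sure40", "risky"), ("sure20", "sure40"), ("zero_a", "risky"), ("zero_a", "sure20")):
        templates += [TrialTemplate("choice", pair)] * 20
    for sid, n in (("sure40", 24), ("sure20", 24), ("risky", 24), ("zero_a", 16), ("zero_b", 16)):
        templates += [TrialTemplate("forced", (sid,))] * n
    templates += [TrialTemplate("choice", ("zero_a", "zero_b"))] * 20
    assert len(templates) == 234
    order = np.random.default_rng(seed).permutation(len(templates))
    return TaskSpec(
        stimuli=stimuli,
        trials=tuple(templates[i] for i in order),
        n_sessions=3,
        reward_scale=reward_scale,
    )


def build_bernoulli_bandit(
    p: Sequence[float],
    r: Sequence[float],
    n_trials: int,
    reward_scale: float = 1.0,
) -> TaskSpec:
    """An all-choice bandit where arm i pays ``r[i]`` with probability ``p[i]``, else 0."""
    if len(p) != len(r):
        raise ValueError(f"p has {len(p)} arms but r has {len(r)}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if any(not 0.0 <= pi <= 1.0 for pi in p):
        raise ValueError("reward probabilities must lie in [0, 1]")
    stimuli = tuple(
        StimulusSpec(
            f"arm{i + 1}", "mixture", values=(float(ri), 0.0), probs=(float(pi), 1.0 - float(pi))
        )
        for i, (pi, ri) in enumerate(zip(p, r))
    )
    offered = tuple(s.id for s in stimuli)
    trials = tuple(TrialTemplate("choice", offered) for _ in range(n_trials))
    return TaskSpec(stimuli=stimuli, trials=trials, reward_scale=reward_scale)


def build_gaussian_bandit(
    mean: float,
    sds: Sequence[float],
    n_trials: int,
    reward_scale: float = 1.0,
) -> TaskSpec:
    """An all-choice bandit whose arms share a mean but differ in outcome sd."""
    if any(sd < 0 for sd in sds):
        raise ValueError("arm sds must be non-negative")
    stimuli = tuple(
        StimulusSpec(f"arm{i + 1}", "gaussian", mean=float(mean), sd=float(sd))
        for i, sd in enumerate(sds)
    )
    offered = tuple(s.id for s in stimuli)
    trials = tuple(TrialTemplate("choice", offered) for _ in range(n_trials))
    return TaskSpec(stimuli=stimuli, trials=trials, reward_scale=reward_scale)


def sample_outcome(
    stimulus: StimulusSpec, rng: np.random.Generator, reward_scale: float = 1.0
) -> float:
    """Draw one payoff from the stimulus, scaled by ``reward_scale``."""
    if stimulus.kind == "fixed":
        out = stimulus.value
    elif stimulus.kind == "mixture":
        u = rng.random()
        acc = 0.0
        out = stimulus.values[-1]
        for v, p in zip(stimulus.values, stimulus.probs):
            acc += p
            if u < acc:
                out = v
                break
    else:
        out = rng.normal(stimulus.mean, stimulus.sd)
    return out * reward_scale


#: named presets accepted by the command line
def get_task(name: str, seed: int = 0, **overrides) -> TaskSpec:
    """Build a named task preset: ``risk234``, ``bandit2`` or ``gauss4``."""
    if name == "risk234":
        return build_risk_task(seed=seed, **overrides)
    if name == "bandit2":
        kw = {"p": (0.8, 0.2), "r": (1.0, 1.0), "n_trials": 500}
        kw.update(overrides)
        return build_bernoulli_bandit(**kw)
    if name == "gauss4":
        kw = {"mean": 250.0, "sds": (0.0, 10.0, 30.0, 70.0), "n_trials": 200}
        kw.update(overrides)
        return build_gaussian_bandit(**kw)
    raise ValueError(f"unknown task preset {name!r}; expected risk234, bandit2 or gauss4")
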