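"""Learning models: value-update and choice-probability rules.

Four Rescorla-Wagner-style models of trial-by-trial choice:

``qlearning``
    Plain delta-rule learning, ``Q <- Q + a'(r - Q)``.
``utility``
    Delta rule on a nonlinear subjective utility of the outcome,
    anchored at U(0)=0, U(20)=20, U(40)=a*20 in task units.
``risk_sensitive``
    Separate learning rates for positive (``alpha_pos``) and negative
    (``alpha_neg``) prediction errors.
``surprise``
    Surprise-sensitive utility: the outcome value is reduced in
    proportion to the absolute prediction error (the surprise),
    ``S = r - d*|r - Q|``, and the delta rule tracks S.

All models share a softmax choice rule with inverse temperature ``beta``
and, by default, a decaying learning rate ``a' = alpha + 0.5/(1 + T_s)``
where ``T_s`` counts how often the outcome of stimulus ``s`` has been
experienced (both free-choice and forced exposures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

MODEL_NAMES: Tuple[str, ...] = ("qlearning", "utility", "risk_sensitive", "surprise")

#: box constraints for every free parameter, shared with the priors
PARAM_BOUNDS: Dict[str, Tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "beta": (0.0, 10.0),
    "d": (-1.0, 1.0),
    "a": (1.0, 30.0),
}

#: free parameters of each model, in canonical order
FREE_PARAMS: Dict[str, Tuple[str, ...]] = {
    "qlearning": ("alpha", "beta"),
    "utility": ("alpha", "beta", "a"),
    "risk_sensitive": ("alpha_pos", "alpha_neg", "beta"),
    "surprise": ("alpha", "beta", "d"),
}


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of one model instance.

    Only the fields listed in ``FREE_PARAMS[model_name]`` are meaningful;
    the rest are ignored and dropped on serialization.
    """

    model_name: str
    alpha: Optional[float] = None
    beta: Optional[float] = None
    d: Optional[float] = None
    alpha_pos: Optional[float] = None
    alpha_neg: Optional[float] = None
    a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}; expected one of {MODEL_NAMES}")
        for name in FREE_PARAMS[self.model_name]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.model_name} requires parameter {name!r}")
            lo, hi = PARAM_BOUNDS[name]
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside its box [{lo}, {hi}]")

    @property
    def free_names(self) -> Tuple[str, ...]:
        return FREE_PARAMS[self.model_name]

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.free_names], dtype=float)

    @classmethod
    def from_vector(cls, model_name: str, theta: Sequence[float]) -> "ModelParams":
        names = FREE_PARAMS[model_name]
        if len(theta) != len(names):
            raise ValueError(f"{model_name} expects {len(names)} parameters, got {len(theta)}")
        return cls(model_name=model_name, **dict(zip(names, (float(v) for v in theta))))

    def to_dict(self) -> Dict[str, float]:
        out: Dict[str, float] = {"model_name": self.model_name}
        for k in self.free_names:
            out[k] = float(getattr(self, k))
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParams":
        data = dict(data)
        name = str(data.pop("model_name"))
        return cls(model_name=name, **{k: float(v) for k, v in data.items()})

    def with_values(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class AgentState:
    """Per-stimulus action values Q and outcome-exposure counts T.

    ``T[s]`` is the number of trials on which the consequence of stimulus
    ``s`` has been experienced; it drives the decaying learning rate.
    """

    Q: Dict[str, float]
    T: Dict[str, int]

    @classmethod
    def initial(cls, stimulus_ids: Iterable[str], q0: float = 0.0) -> "AgentState":
        ids = list(stimulus_ids)
        return cls(Q={s: float(q0) for s in ids}, T={s: 0 for s in ids})

    def copy(self) -> "AgentState":
        return AgentState(Q=dict(self.Q), T=dict(self.T))


def decayed_learning_rate(alpha: float, t_s: int, clip: bool = False) -> float:
    """Effective learning rate ``alpha + 0.5/(1 + T_s)``.

    Strictly decreasing in ``t_s`` and converging to ``alpha``. With
    ``clip`` the result is capped at 1 (the raw formula exceeds 1 on
    early trials whenever ``alpha > 0.5``).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if t_s < 0 or int(t_s) != t_s:
        raise ValueError(f"T_s must be a non-negative integer, got {t_s}")
    rate = alpha + 0.5 / (1.0 + t_s)
    if clip and rate > 1.0:
        return 1.0
    return rate


def surprise_utility(r: float, q: float, d: float) -> float:
    """Surprise-modulated subjective utility ``S = r - d*|r - q|``.

    The surprise is the absolute prediction error; ``d`` is the surprise
    decay rate. ``d > 0`` devalues surprising outcomes of either valence,
    ``d = 0`` recovers the objective outcome.
    """
    if not (math.isfinite(r) and math.isfinite(q)):
        raise ValueError("r and q must be finite")
    if not -1.0 <= d <= 1.0:
        raise ValueError(f"d={d} outside [-1, 1]")
    return r - d * abs(r - q)


def utility_transform(r: float, a: float, continuous: bool = False, unit: float = 20.0) -> float:
    """Nonlinear subjective utility with anchors U(0)=0, U(unit)=unit, U(2*unit)=a*unit.

    By default the outcome must lie on the three-point support
    ``{0, unit, 2*unit}`` (the risky-task payoffs, unit = 20 cents). With
    ``continuous=True`` the anchors are interpolated by the power law
    ``U(x) = unit * (x/unit)**log2(a)`` (odd-extended to negative x),
    which coincides with the table on the discrete support and is the
    extension used for Gaussian-outcome tasks.
    """
    if not 1.0 <= a <= 30.0:
        raise ValueError(f"a={a} outside [1, 30]")
    if unit <= 0:
        raise ValueError("unit must be positive")
    if continuous:
        if r == 0.0:
            return 0.0
        sign = 1.0 if r > 0 else -1.0
        return sign * unit * math.pow(abs(r) / unit, math.log2(a))
    if r == 0.0:
        return 0.0
    if r == unit:
        return unit
    if r == 2.0 * unit:
        return a * unit
    raise ValueError(f"r={r} outside the discrete utility support {{0, {unit}, {2 * unit}}}")


def _rate_and_target(
    params: ModelParams,
    q: float,
    t_s: int,
    r: float,
    decay: bool,
    clip: bool,
    unit: float,
) -> Tuple[float, float]:
    """Effective learning rate and update target for one experienced outcome."""
    model = params.model_name
    if model == "risk_sensitive":
        delta = r - q
        base = params.alpha_pos if delta > 0 else params.alpha_neg
        target = r
    else:
        base = params.alpha
        if model == "qlearning":
            target = r
        elif model == "surprise":
            target = surprise_utility(r, q, params.d)
        else:  # utility
            target = utility_transform(r, params.a, continuous=True, unit=unit)
    rate = decayed_learning_rate(base, t_s, clip) if decay else base
    return rate, target


def update_state(
    state: AgentState,
    params: ModelParams,
    stimulus: str,
    r: float,
    *,
    decay: bool = True,
    clip: bool = False,
    utility_unit: float = 20.0,
    inplace: bool = False,
) -> AgentState:
    """Advance the agent state after experiencing outcome ``r`` for ``stimulus``.

    Only the experienced stimulus changes: its Q moves toward the
    model-specific target by the effective learning rate (computed from
    the pre-update exposure count) and its exposure count increments.
    """
    if stimulus not in state.Q:
        raise KeyError(f"unknown stimulus {stimulus!r}")
    if not math.isfinite(r):
        raise ValueError("reward must be finite")
    new = state if inplace else state.copy()
    q = new.Q[stimulus]
    rate, target = _rate_and_target(params, q, new.T[stimulus], r, decay, clip, utility_unit)
    new.Q[stimulus] = q + rate * (target - q)
    new.T[stimulus] += 1
    return new


def _choice_probs(q_values: Sequence[float], beta: float) -> list:
    """Stable softmax over raw action values (internal fast path)."""
    zs = [beta * q for q in q_values]
    m = max(zs)
    es = [math.exp(z - m) for z in zs]
    total = sum(es)
    return [e / total for e in es]


def choice_probabilities(
    state: AgentState, params: ModelParams, offered: Sequence[str]
) -> np.ndarray:
    """Softmax choice probabilities over the offered stimuli.

    ``P(i) = exp(beta*Q_i) / sum_j exp(beta*Q_j)``, computed with
    max-subtraction so it is invariant to adding a constant to all Q.
    """
    if len(offered) == 0:
        raise ValueError("offered set must be non-empty")
    qs = [state.Q[s] for s in offered]
    return np.asarray(_choice_probs(qs, params.beta))
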