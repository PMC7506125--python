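"""MAP fitting and Laplace model evidence.

Fits any of the four models to one subject's session by maximum a
posteriori estimation under weakly informative priors (Beta(2,2) on
learning rates, Gamma(shape 2, scale 3) on the inverse temperature,
uniform on the utility curvature and the surprise decay rate), and
approximates the log marginal likelihood with the Laplace method:

    log p(D|M) ~= log p(D, theta_hat | M) + (k/2) log 2*pi
                  - (1/2) log det H

where H is the Hessian of the negative log posterior at the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .models import (
    FREE_PARAMS,
    PARAM_BOUNDS,
    ModelParams,
    _choice_probs,
    _rate_and_target,
)
from .simulate import SessionData

_LOG_2PI = math.log(2.0 * math.pi)


class PriorSpec:
    """Per-parameter prior distributions on the models' box supports.

    Densities are the untruncated scipy distributions; the box is
    enforced by the optimizer, so normalization constants shared across
    models cancel in evidence comparisons and MAP locations are
    unaffected. The Gamma prior on beta is parameterized by shape and
    scale by default (mode 3 inside the [0, 10] box); ``gamma_rate=True``
    switches to the shape/rate reading.
    """

    def __init__(self, distributions: Optional[Dict[str, object]] = None, gamma_rate: bool = False):
        beta_scale = (1.0 / 3.0) if gamma_rate else 3.0
        self.distributions: Dict[str, object] = {
            "alpha": stats.beta(2, 2),
            "alpha_pos": stats.beta(2, 2),
            "alpha_neg": stats.beta(2, 2),
            "beta": stats.gamma(2, scale=beta_scale),
            "a": stats.uniform(1.0, 29.0),
            "d": stats.uniform(-1.0, 2.0),
        }
        if distributions:
            self.distributions.update(distributions)

    def logpdf(self, name: str, value: float) -> float:
        lo, hi = PARAM_BOUNDS[name]
        if not lo <= value <= hi:
            return -math.inf
        return float(self.distributions[name].logpdf(value))

    def sample(self, name: str, rng: np.random.Generator) -> float:
        """One draw from the prior, rejection-truncated to the parameter box."""
        lo, hi = PARAM_BOUNDS[name]
        dist = self.distributions[name]
        for _ in range(1000):
            x = float(dist.rvs(random_state=rng))
            if lo < x < hi:
                return x
        raise RuntimeError(f"could not draw {name} inside [{lo}, {hi}] from its prior")


def default_priors(gamma_rate: bool = False) -> PriorSpec:
    return PriorSpec(gamma_rate=gamma_rate)


def _compiled(session: SessionData):
    """Index-based replay representation, cached on the session."""
    cached = session.__dict__.get("_compiled")
    if cached is not None:
        return cached
    idx = {sid: i for i, sid in enumerate(session.task.stimulus_ids)}
    rows = tuple(
        (
            t.trial_type == "choice",
            tuple(idx[o] for o in t.offered),
            idx[t.choice],
            float(t.reward),
        )
        for t in session.trials
    )
    session.__dict__["_compiled"] = rows
    return rows


def session_log_likelihood(
    params: ModelParams,
    session: SessionData,
    *,
    decay: bool = True,
    clip: bool = False,
    q0: float = 0.0,
) -> float:
    """Log likelihood of the recorded choices under the model.

    Replays the session in order: choice trials contribute the log
    softmax probability of the recorded choice; forced trials contribute
    no likelihood term; every trial (forced or choice) updates the state
    with the recorded reward. Evaluation is side-effect-free.
    """
    rows = _compiled(session)
    n_stim = len(session.task.stimulus_ids)
    Q = [q0] * n_stim
    T = [0] * n_stim
    unit = 20.0 * session.task.reward_scale
    beta = params.beta
    ll = 0.0
    for is_choice, offered, c, r in rows:
        if is_choice:
            if len(offered) == 2:
                i, j = offered
                x = beta * Q[i]
                y = beta * Q[j]
                m = x if x > y else y
                lse = m + math.log(math.exp(x - m) + math.exp(y - m))
                ll += (x if c == i else y) - lse
            else:
                zs = [beta * Q[k] for k in offered]
                m = max(zs)
                lse = m + math.log(sum(math.exp(z - m) for z in zs))
                ll += beta * Q[c] - lse
        q = Q[c]
        rate, target = _rate_and_target(params, q, T[c], r, decay, clip, unit)
        Q[c] = q + rate * (target - q)
        T[c] += 1
    return ll


def log_posterior(
    params: ModelParams,
    session: SessionData,
    priors: PriorSpec,
    *,
    decay: bool = True,
    clip: bool = False,
    q0: float = 0.0,
) -> float:
    """Unnormalized log posterior: log likelihood plus log prior densities.

    Returns ``-inf`` outside the prior support.
    """
    lp = 0.0
    for name in params.free_names:
        lp += priors.logpdf(name, getattr(params, name))
        if lp == -math.inf:
            return -math.inf
    return lp + session_log_likelihood(params, session, decay=decay, clip=clip, q0=q0)


@dataclass
class LaplaceResult:
    log_evidence: float
    hessian_logdet: float
    regularized: bool


def _finite_difference_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Hessian, with steps shrunk near box edges."""
    k = len(x)
    h = np.array([rel_step * max(1.0, abs(xi)) for xi in x])
    if bounds is not None:
        for i, (lo, hi) in enumerate(bounds):
            # keep all evaluation points strictly inside the support
            room = min(x[i] - lo, hi - x[i])
            if room > 0:
                h[i] = min(h[i], 0.49 * room)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def laplace_log_evidence(
    neg_log_posterior: Callable[[np.ndarray], float],
    theta_hat: np.ndarray,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    rel_step: float = 1e-4,
) -> LaplaceResult:
    """Laplace approximation to the log marginal likelihood at an interior mode.

    A Hessian that is not positive definite is ridged up to the smallest
    eigenvalue plus a margin and the result flagged ``regularized``.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    H = _finite_difference_hessian(neg_log_posterior, theta_hat, bounds, rel_step)
    H = 0.5 * (H + H.T)
    eigvals = np.linalg.eigvalsh(H)
    regularized = False
    if eigvals[0] <= 0:
        H = H + (abs(eigvals[0]) + 1e-6) * np.eye(len(theta_hat))
        regularized = True
    sign, logdet = np.linalg.slogdet(H)
    k = len(theta_hat)
    log_ev = -neg_log_posterior(theta_hat) + 0.5 * k * _LOG_2PI - 0.5 * logdet
    return LaplaceResult(log_evidence=float(log_ev), hessian_logdet=float(logdet), regularized=regularized)


@dataclass
class FitResult:
    """MAP fit of one model to one session, with Laplace evidence."""

    model_name: str
    params_hat: ModelParams
    log_posterior: float
    log_likelihood: float
    log_evidence: float
    hessian_logdet: float
    n_params: int
    converged: bool
    boundary: bool
    regularized: bool
    n_restarts_used: int
    seed: Optional[int] = None
    subject_id: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "model_name": self.model_name,
            "params_hat": self.params_hat.to_dict(),
            "log_posterior": self.log_posterior,
            "log_likelihood": self.log_likelihood,
            "log_evidence": self.log_evidence,
            "hessian_logdet": self.hessian_logdet,
            "n_params": self.n_params,
            "converged": self.converged,
            "boundary": self.boundary,
            "regularized": self.regularized,
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "subject_id": self.subject_id,
        }
        return d


_BOUND_EPS = 1e-6  # optimizer box inset: prior densities vanish at some edges
_BOUNDARY_TOL = 1e-4  # mode closer than this to an edge counts as a boundary fit


def map_fit(
    model: str,
    session: SessionData,
    priors: Optional[PriorSpec] = None,
    n_restarts: int = 10,
    seed: int = 0,
    *,
    decay: bool = True,
    clip: bool = False,
    q0: float = 0.0,
) -> FitResult:
    """Box-constrained MAP estimation with prior-sampled multistart.

    Maximizes the log posterior with L-BFGS-B from ``n_restarts`` start
    points drawn from the priors, keeps the best optimum, and computes
    the Laplace log evidence there. A mode within 1e-4 of a box edge is
    nudged inward before the Hessian evaluation and flagged ``boundary``.
    Deterministic given ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if model not in FREE_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    if priors is None:
        priors = default_priors()
    names = FREE_PARAMS[model]
    bounds = [PARAM_BOUNDS[n] for n in names]
    opt_bounds = [(lo + _BOUND_EPS, hi - _BOUND_EPS) for lo, hi in bounds]

    def neg_log_post(theta: np.ndarray) -> float:
        try:
            p = ModelParams.from_vector(model, theta)
        except ValueError:
            return 1e12
        lp = log_posterior(p, session, priors, decay=decay, clip=clip, q0=q0)
        if not math.isfinite(lp):
            return 1e12
        return -lp

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for _ in range(n_restarts):
        x0 = np.array([priors.sample(n, rng) for n in names])
        x0 = np.clip(x0, [b[0] for b in opt_bounds], [b[1] for b in opt_bounds])
        res = optimize.minimize(neg_log_post, x0, method="L-BFGS-B", bounds=opt_bounds)
        if not math.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"map_fit({model}): all {n_restarts} restarts failed to produce a finite optimum"
        )

    theta = np.asarray(best.x, dtype=float)
    boundary = False
    for i, (lo, hi) in enumerate(bounds):
        if theta[i] - lo < _BOUNDARY_TOL:
            theta[i] = lo + _BOUNDARY_TOL
            boundary = True
        elif hi - theta[i] < _BOUNDARY_TOL:
            theta[i] = hi - _BOUNDARY_TOL
            boundary = True

    lap = laplace_log_evidence(neg_log_post, theta, bounds=bounds)
    params_hat = ModelParams.from_vector(model, theta)
    lp_hat = -neg_log_post(theta)
    ll_hat = session_log_likelihood(params_hat, session, decay=decay, clip=clip, q0=q0)
    return FitResult(
        model_name=model,
        params_hat=params_hat,
        log_posterior=float(lp_hat),
        log_likelihood=float(ll_hat),
        log_evidence=lap.log_evidence,
        hessian_logdet=lap.hessian_logdet,
        n_params=len(names),
        converged=bool(best.success) and n_ok > 0,
        boundary=boundary,
        regularized=lap.regularized,
        n_restarts_used=n_restarts,
        seed=seed,
        subject_id=session.subject_id,
    )
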