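"""Random-effects Bayesian model selection from per-subject log evidences.

Implements the variational Dirichlet-multinomial scheme for group model
comparison: a Dirichlet posterior over model frequencies in the
population, exceedance probabilities (probability a model is the most
frequent), the Bayes omnibus risk (posterior probability that all models
are equally frequent), and the protected exceedance probability

    pxp_k = (1 - BOR) * xp_k + BOR / K,

which hedges the exceedance probability against the null of equal
frequencies. Also provides the one-sample t-test used to test whether a
fitted parameter is significantly different from a reference value
across subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import betainc, digamma, expit, gammaln, logsumexp


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x models grid of log marginal likelihoods (nats)."""

    values: np.ndarray
    subjects: Tuple[str, ...]
    models: Tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape != (len(self.subjects), len(self.models)):
            raise ValueError("evidence shape must be (n_subjects, n_models)")
        if v.shape[1] < 2 or v.shape[0] < 1:
            raise ValueError("need >= 2 models and >= 1 subject")
        if not np.all(np.isfinite(v)):
            raise ValueError("log evidences must be finite")

    @classmethod
    def from_array(cls, values, models: Optional[Sequence[str]] = None,
                   subjects: Optional[Sequence[str]] = None) -> "EvidenceMatrix":
        v = np.asarray(values, dtype=float)
        n, k = v.shape
        return cls(
            values=v,
            subjects=tuple(subjects) if subjects is not None else tuple(f"S{i+1:03d}" for i in range(n)),
            models=tuple(models) if models is not None else tuple(f"M{j+1}" for j in range(k)),
        )


@dataclass(frozen=True)
class BMSResult:
    models: Tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    responsibilities: np.ndarray
    free_energy: float
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "xp": self.xp.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
            "free_energy": self.free_energy,
            "n_iter": self.n_iter,
        }


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dirichlet(alpha) || Dirichlet(alpha0))."""
    asum = alpha.sum()
    return float(
        gammaln(asum)
        - gammaln(alpha).sum()
        - gammaln(alpha0.sum())
        + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(asum))).sum()
    )


def vb_dirichlet(
    evidence: "EvidenceMatrix | np.ndarray",
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> Tuple[np.ndarray, np.ndarray, float, int]:
    """Variational posterior over population model frequencies.

    Fixed-point iteration: per-subject responsibilities
    ``g_nk proportional to exp(l_nk + psi(alpha_k) - psi(sum alpha))``,
    then ``alpha_k = alpha0 + sum_n g_nk``, until the largest change in
    alpha falls below ``tol``. Returns ``(alpha, g, F, n_iter)`` where F
    is the converged variational free energy (the evidence bound for the
    hypothesis that frequencies vary across the population).
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    L = evidence.values if isinstance(evidence, EvidenceMatrix) else np.asarray(evidence, float)
    n, k = L.shape
    a0 = np.full(k, float(alpha0))
    alpha = a0.copy()
    for it in range(1, max_iter + 1):
        logg = L + digamma(alpha) - digamma(alpha.sum())
        logg = logg - logsumexp(logg, axis=1, keepdims=True)
        g = np.exp(logg)
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(
            f"vb_dirichlet did not converge in {max_iter} iterations (last alpha={alpha})"
        )
    # free energy of the converged posterior
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_g = -np.where(g > 0, g * np.log(g), 0.0).sum()
    free_energy = float((g * (L + elog_r)).sum() + entropy_g - _dirichlet_kl(alpha, a0))
    return alpha, g, free_energy, it


def exceedance_prob(
    dirichlet_alpha: Sequence[float],
    n_samples: int = 1_000_000,
    seed: Optional[int] = 0,
    exact_k2: bool = False,
) -> np.ndarray:
    """P(model k is the most frequent) under the Dirichlet posterior.

    Monte Carlo by default; for K=2 the exact Beta tail
    ``P(r_1 > 1/2) = 1 - I_{1/2}(alpha_1, alpha_2)`` is available.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet counts must be positive")
    k = len(alpha)
    if exact_k2:
        if k != 2:
            raise ValueError("exact exceedance is only available for K=2")
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    wins = np.zeros(k, dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        chunk = min(remaining, 250_000)
        draws = rng.dirichlet(alpha, size=chunk)
        wins += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= chunk
    return wins / float(n_samples)


def bayes_omnibus_risk(
    evidence: "EvidenceMatrix | np.ndarray",
    free_energy: float,
) -> float:
    """Posterior probability that all models are equally frequent.

    Compares the variational free energy ``F1`` of the random-frequency
    hypothesis with the exact evidence ``F0`` of the null (frequencies
    fixed at 1/K): ``BOR = 1 / (1 + exp(F1 - F0))``.
    """
    L = evidence.values if isinstance(evidence, EvidenceMatrix) else np.asarray(evidence, float)
    n, k = L.shape
    f0 = float(logsumexp(L, axis=1).sum() - n * math.log(k))
    return float(expit(f0 - free_energy))


def protected_xp(xp: Sequence[float], bor: float) -> np.ndarray:
    """Exceedance probabilities hedged by the equal-frequency null."""
    xp = np.asarray(xp, dtype=float)
    if not 0.0 <= bor <= 1.0:
        raise ValueError("bor must lie in [0, 1]")
    if abs(xp.sum() - 1.0) > 1e-6:
        raise ValueError("xp must sum to 1")
    return (1.0 - bor) * xp + bor / len(xp)


def bms(
    evidence: "EvidenceMatrix | np.ndarray",
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: Optional[int] = 0,
    exact_k2: bool = False,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Full group-level comparison: Dirichlet posterior, XP, BOR, protected XP."""
    if not isinstance(evidence, EvidenceMatrix):
        evidence = EvidenceMatrix.from_array(evidence)
    alpha, g, f1, n_iter = vb_dirichlet(evidence, alpha0=alpha0, tol=tol, max_iter=max_iter)
    xp = exceedance_prob(alpha, n_samples=n_samples, seed=seed,
                         exact_k2=exact_k2 and len(alpha) == 2)
    bor = bayes_omnibus_risk(evidence, f1)
    return BMSResult(
        models=evidence.models,
        dirichlet_alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        responsibilities=g,
        free_energy=f1,
        xp=xp,
        bor=bor,
        pxp=protected_xp(xp, bor),
        n_iter=n_iter,
    )


def one_sample_t(values: Sequence[float], null: float = 0.0) -> Tuple[float, int, float]:
    """Classical one-sample t-test of the mean against ``null``.

    Returns ``(t, df, two-sided p)``. A zero-variance sample gives t = 0
    when every value equals the null and signed infinity otherwise.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == null:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean - null), df, 0.0
    t = (mean - null) / (sd / math.sqrt(n))
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), df, float(p)
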