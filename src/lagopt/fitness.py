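"""Geometric-mean fitness of lag-time strategies under stochastic antibiotics.

Every function here returns the long-term average log-growth per
inoculation round, relative to a zero-lag antibiotic-free population:
the expectation of ``ln f(T)`` over the Bernoulli(p) application of the
antibiotic and, when relevant, over the duration distribution q(T).
Fitness is therefore never positive, and equals zero only when the
antibiotic has no effect and all mass wakes instantly.

Layers, from concrete to general:

- single exponential phenotype, fixed duration (``fitness_single_fixed_t``)
- single phenotype, distributed duration (``fitness_single_distributed_t``)
- two phenotypes sharing the environment (``fitness_two_phenotype``)
- arbitrary lag-time distribution r(l) as a functional
  (``growth_factor_general``, ``fitness_functional``)
- its bin discretization F_d and the ``h`` coefficients whose
  r-averages are exactly the arguments of F_d's logarithms
  (``fitness_discretized``, ``h_coefficient``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate
from scipy.special import logsumexp

from .distributions import DiscretizedLagDistribution, DurationDistribution
from .growth import log_growth_factor_exp

__all__ = [
    "AntibioticRegime",
    "FitnessValue",
    "fitness_single_fixed_t",
    "fitness_single_distributed_t",
    "fitness_two_phenotype",
    "growth_factor_general",
    "fitness_functional",
    "fitness_discretized",
    "h_coefficient",
    "h_matrix",
    "effective_bin_weights",
]


@dataclass(frozen=True)
class AntibioticRegime:
    """Environment: application probability ``p``, kill rate ``gamma``, and
    either a fixed duration (float) or a :class:`DurationDistribution`."""

    p: float
    gamma: float
    duration: float | DurationDistribution

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"application probability p must be in [0, 1], got {self.p}")
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError(f"kill rate gamma must be finite and >= 0, got {self.gamma}")
        if isinstance(self.duration, (int, float)) and self.duration < 0:
            raise ValueError("fixed duration T must be >= 0")


@dataclass(frozen=True)
class FitnessValue:
    """Per-round log fitness split into its no-antibiotic and antibiotic parts."""

    total: float
    no_antibiotic_term: float
    antibiotic_term: float


def _check_p(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"application probability p must be in [0, 1], got {p}")


def log_growth_factor_boundary(gamma: float, T) -> np.ndarray | float:
    """``lim_{λ→0} ln f(T) = -(1 + γ) T``: instant wake-up, full exposure."""
    return -(1.0 + gamma) * np.asarray(T, dtype=float)


def fitness_single_fixed_t(lam: float, gamma: float, p: float, T: float) -> FitnessValue:
    """Fitness of a single exponential phenotype under a fixed duration.

    ``F = (1-p) ln[1/(1+λ)] + p ln f(T)``; at ``λ = 0`` the boundary
    limit ``-p (1+γ) T`` is returned.
    """
    _check_p(p)
    if lam == 0:
        no_ab, ab = 0.0, p * float(log_growth_factor_boundary(gamma, T))
    else:
        no_ab = -(1.0 - p) * np.log1p(lam)
        ab = p * log_growth_factor_exp(lam, gamma, T)
    return FitnessValue(total=no_ab + ab, no_antibiotic_term=no_ab, antibiotic_term=float(ab))


def fitness_single_distributed_t(
    lam: float, gamma: float, p: float, q: DurationDistribution
) -> FitnessValue:
    """Fitness of a single phenotype when the duration T is drawn from q.

    The duration average runs over q's bins at their representative
    points: ``(1-p) ln f(0) + p Σ_m q_m ln f(mΔ)``.
    """
    _check_p(p)
    Tm = q.duration_grid
    if lam == 0:
        lnf = log_growth_factor_boundary(gamma, Tm)
        no_ab = 0.0
    else:
        lnf = log_growth_factor_exp(lam, gamma, Tm)
        no_ab = -(1.0 - p) * np.log1p(lam)
    ab = p * float(q.weights @ lnf)
    return FitnessValue(total=no_ab + ab, no_antibiotic_term=no_ab, antibiotic_term=ab)


def _lnf_or_boundary(lam: float, gamma: float, T: float) -> float:
    if lam == 0:
        return float(log_growth_factor_boundary(gamma, T))
    return float(log_growth_factor_exp(lam, gamma, T))


def fitness_two_phenotype(
    x: float, lam_a: float, lam_b: float, gamma: float, p: float, T: float
) -> FitnessValue:
    """Fitness of a population split into fractions ``1-x`` (lag ``λ_a``)
    and ``x`` (lag ``λ_b``) sharing every round:

    ``F = p ln[(1-x) f_a(T) + x f_b(T)] + (1-p) ln[(1-x) f_a(0) + x f_b(0)]``

    The growth factors mix *inside* the logarithm — the subpopulations
    are pooled before the round outcome is scored, which is what makes
    bet-hedging pay.
    """
    _check_p(p)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"fraction x must be in [0, 1], got {x}")
    weights = np.array([1.0 - x, x])
    ln_T = np.array([_lnf_or_boundary(lam_a, gamma, T), _lnf_or_boundary(lam_b, gamma, T)])
    ln_0 = np.array([-np.log1p(lam_a), -np.log1p(lam_b)])
    ab = p * float(logsumexp(ln_T, b=weights)) if p > 0 else 0.0
    no_ab = (1.0 - p) * float(logsumexp(ln_0, b=weights)) if p < 1 else 0.0
    return FitnessValue(total=ab + no_ab, no_antibiotic_term=no_ab, antibiotic_term=ab)


def h_coefficient(n, m, gamma: float, delta: float):
    """Discretization weight ``h_n^m``: contribution of lag bin ``n`` to the
    growth factor of a round with duration ``mΔ``::

        h_n^m = exp[-mΔ - γ(m-n)Δ]   (n < m: woke under the antibiotic)
                exp[-nΔ]             (otherwise: woke after it ended)

    Strictly positive and bounded by 1. The r-average ``<h^m>`` equals
    the argument of the m-th logarithm of the discretized fitness F_d.
    """
    n = np.asarray(n)
    m = np.asarray(m)
    return np.where(
        n < m,
        np.exp(-m * delta - gamma * (m - n) * delta),
        np.exp(-n * delta),
    )


def h_matrix(n_bins: int, gamma: float, delta: float) -> np.ndarray:
    """Matrix ``H[n, m] = h_n^m`` for ``n, m = 0 .. n_bins-1``."""
    idx = np.arange(n_bins)
    return h_coefficient(idx[:, None], idx[None, :], gamma, delta)


def effective_bin_weights(q_weights: np.ndarray, p: float) -> np.ndarray:
    """Weights ``w_m`` multiplying ``ln <h^m>`` in F_d.

    ``w_0 = (1-p) + p q_0`` and ``w_m = p q_m`` for ``m >= 1``: a round
    without antibiotic and a round of zero duration contribute the same
    logarithm, so the no-antibiotic probability folds into the m = 0 bin.
    These are also the weights of the KKT stationarity condition
    ``1 - μ_n = Σ_m w_m h_n^m / <h^m>``.
    """
    _check_p(p)
    w = p * np.asarray(q_weights, dtype=float)
    w[0] += 1.0 - p
    return w


def growth_factor_general(
    r: DiscretizedLagDistribution | Callable[[np.ndarray], np.ndarray],
    gamma: float,
    T: float,
) -> float:
    """``ln f(T)[r]`` for an arbitrary lag-time distribution r(l)::

        ln[ e^{-(1+γ)T} ∫_0^T e^{γl} r(l) dl  +  ∫_T^∞ e^{-l} r(l) dl ]

    The first integral collects cells that woke while the antibiotic was
    present (they decayed until T, then grew), the second those that
    slept through it (pure delay cost ``e^{-l}``). A binned ``r`` uses
    its representative points (bins with ``nΔ < T`` count as exposed);
    a callable density is integrated by quadrature with the tail
    truncated where ``e^{-l}`` is negligible.
    """
    if isinstance(r, DiscretizedLagDistribution):
        l = r.lag_grid
        exposed = l < T
        a1 = np.exp(-(1.0 + gamma) * T) * float(
            np.exp(gamma * l[exposed]) @ r.weights[exposed]
        )
        a2 = float(np.exp(-l[~exposed]) @ r.weights[~exposed])
        return float(np.log(a1 + a2))
    # callable density
    if T > 0:
        i1, _ = integrate.quad(lambda l: np.exp(gamma * l) * r(l), 0.0, T, limit=200)
    else:
        i1 = 0.0
    upper = T + 60.0  # e^{-l} tail beyond this is < 1e-26 of the integrand scale
    i2, _ = integrate.quad(lambda l: np.exp(-l) * r(l), T, upper, limit=200)
    val = np.exp(-(1.0 + gamma) * T) * i1 + i2
    if val <= 0:
        raise ValueError("growth factor is non-positive; is r a valid density?")
    return float(np.log(val))


def fitness_functional(
    r: DiscretizedLagDistribution | Callable[[np.ndarray], np.ndarray],
    q: DurationDistribution | Callable[[np.ndarray], np.ndarray],
    gamma: float,
    p: float,
    t_max: float | None = None,
) -> FitnessValue:
    """General fitness ``F[r, q] = (1-p) ln f(0)[r] + p E_q[ln f(T)[r]]``.

    ``q`` may be a binned :class:`DurationDistribution` (the duration
    average is a sum over bins) or a callable density on ``[0, t_max]``
    (quadrature; ``t_max`` required).
    """
    _check_p(p)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    no_ab = (1.0 - p) * growth_factor_general(r, gamma, 0.0)
    if isinstance(q, DurationDistribution):
        ab = p * sum(
            qm * growth_factor_general(r, gamma, float(Tm))
            for qm, Tm in zip(q.weights, q.duration_grid)
            if qm > 0
        )
    else:
        if t_max is None:
            raise ValueError("t_max is required when q is a callable density")
        norm, _ = integrate.quad(q, 0.0, t_max, limit=200)
        ab_raw, _ = integrate.quad(
            lambda T: q(T) * growth_factor_general(r, gamma, T), 0.0, t_max, limit=200
        )
        ab = p * ab_raw / norm
    return FitnessValue(total=no_ab + ab, no_antibiotic_term=no_ab, antibiotic_term=float(ab))


def fitness_discretized(
    r_weights: np.ndarray,
    q_weights: np.ndarray,
    gamma: float,
    p: float,
    delta: float,
    _H: np.ndarray | None = None,
) -> FitnessValue:
    """Discretized fitness F_d on matched r and q bin vectors::

        F_d = (1-p) ln[Σ_n e^{-nΔ} r_n]
              + p Σ_m q_m ln[e^{-(1+γ)mΔ} Σ_{n<m} e^{γnΔ} r_n + Σ_{n>=m} e^{-nΔ} r_n]

    computed as ``Σ_m w_m ln <h^m>`` with the effective weights ``w``
    (the m-th log argument is exactly the r-average of ``h^m``).
    ``_H`` lets hot loops pass a precomputed ``h_matrix``.
    """
    r = np.asarray(r_weights, dtype=float)
    q = np.asarray(q_weights, dtype=float)
    if len(r) != len(q):
        raise ValueError(f"r and q must have equal length, got {len(r)} and {len(q)}")
    for name, v in (("r", r), ("q", q)):
        if np.any(v < -1e-9) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} weights must lie on the simplex")
    H = h_matrix(len(r), gamma, delta) if _H is None else _H
    hm = r @ H
    w = effective_bin_weights(q, p)
    with np.errstate(divide="ignore"):
        log_hm = np.log(hm)
    active = w > 0
    total = float(w[active] @ log_hm[active])
    no_ab = (1.0 - p) * float(log_hm[0])
    return FitnessValue(total=total, no_antibiotic_term=no_ab, antibiotic_term=total - no_ab)
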