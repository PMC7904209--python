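"""Single-round population dynamics of the dormancy/growth model.

One inoculation round starts with the whole population dormant. Dormant
cells are fully tolerant to the antibiotic and wake up into the growing
state; growing cells die at rate ``gamma`` while the antibiotic is present
(``t < T``) and grow at rate 1 (the unit of time) afterwards. For a
single-step wake-up the waiting time is exponential with mean ``lam``;
an ``M``-step sequential wake-up gives an Erlang waiting time with the
same mean.

The long-time population behaves as ``f(T) * exp(t)``; the growth factor
``f(T)`` measures the combined cost of the antibiotic and of the lag
relative to a zero-lag, antibiotic-free population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "Phenotype",
    "RoundState",
    "RoundTrajectory",
    "log_growth_factor_exp",
    "integrate_single_round",
    "erlang_lag_pdf",
]


@dataclass(frozen=True)
class Phenotype:
    """A wake-up strategy: mean lag time and number of sequential dormant states.

    Parameters
    ----------
    lam:
        Mean lag time ``λ ≥ 0`` in units of the inverse growth rate.
    m:
        Number of sequential dormant states (Erlang shape), ``M ≥ 1``.
        ``M = 1`` gives an exponential lag-time distribution.
    """

    lam: float
    m: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"mean lag time must be finite and >= 0, got {self.lam}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"number of dormant states must be an integer >= 1, got {self.m}")


@dataclass
class RoundState:
    """Population masses at one time point of a round.

    ``d`` is the vector of dormant masses over the ``M`` sequential states,
    ``g`` the growing mass, ``t`` the elapsed time since inoculation.
    """

    d: np.ndarray
    g: float
    t: float

    @property
    def d_total(self) -> float:
        return float(np.sum(self.d))


@dataclass
class RoundTrajectory:
    """Sampled trajectory of one inoculation round plus its asymptotic readout."""

    times: np.ndarray
    d: np.ndarray  # shape (n_times, M)
    g: np.ndarray  # shape (n_times,)
    log_rel_growth: float  # ln[g(t_end) / e^{t_end}], the finite-time estimate of ln f(T)

    def state(self, i: int) -> RoundState:
        return RoundState(d=self.d[i], g=float(self.g[i]), t=float(self.times[i]))


def _log_abs_exp_diff(a, b):
    """log|e^a - e^b| computed without cancellation; -inf when a == b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    hi = np.maximum(a, b)
    diff = -np.abs(a - b)
    with np.errstate(divide="ignore"):
        return hi + np.log(-np.expm1(diff))


def log_growth_factor_exp(lam: float, gamma: float, T) -> np.ndarray | float:
    """Log growth factor ``ln f(T)`` of the single-step (exponential lag) model.

    Closed form::

        ln f(T) = -T + ln[ (e^{-T/λ} - e^{-γT}) / (γλ - 1) + e^{-T/λ} / (1 + λ) ]

    evaluated in log space so large ``T/λ`` or ``γT`` never underflow.  The
    removable singularity at ``γλ = 1`` is crossed with an ``expm1``
    rewrite of the first term (its analytic limit is ``(T/λ) e^{-γT}``),
    so no accuracy is lost near ``γλ = 1``.

    Parameters
    ----------
    lam:
        Mean lag time ``λ > 0``. The ``λ = 0`` boundary is not in this
        function's domain; the fitness module carries the boundary limit.
    gamma:
        Kill rate ``γ ≥ 0`` of growing cells under the antibiotic.
    T:
        Antibiotic application duration(s), ``T ≥ 0``; scalar or array.

    Returns
    -------
    ``ln f(T)``, scalar if ``T`` is scalar.
    """
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be finite and > 0, got {lam}")
    if not (np.isfinite(gamma) and gamma >= 0):
        raise ValueError(f"gamma must be finite and >= 0, got {gamma}")
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr < 0) or not np.all(np.isfinite(T_arr)):
        raise ValueError("durations T must be finite and >= 0")

    # log of term1 = (e^{-T/λ} - e^{-γT}) / (γλ - 1), always >= 0.
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        c = gamma - 1.0 / lam  # (γλ - 1) / λ
        x = c * T_arr
        small = np.abs(x) < 0.5
        # near the singularity: term1 = e^{-T/λ} (T/λ) ψ(x), ψ(x) = -expm1(-x)/x -> 1
        xs = np.where(small & (x != 0), x, 1.0)
        psi = np.where(x == 0, 1.0, -np.expm1(-xs) / xs)
        log_t1_small = -T_arr / lam + np.log(T_arr / lam) + np.log(psi)
        log_t1_far = _log_abs_exp_diff(-T_arr / lam, -gamma * T_arr) - np.log(
            np.abs(gamma * lam - 1.0)
        )
        log_t1 = np.where(small, log_t1_small, log_t1_far)
        log_t1 = np.where(T_arr == 0, -np.inf, log_t1)
        log_t2 = -T_arr / lam - np.log1p(lam)
        out = -T_arr + np.logaddexp(log_t1, log_t2)
    return out.item() if np.isscalar(T) or T_arr.ndim == 0 else out


def _wakeup_generator(phen: Phenotype, growth_rate: float) -> np.ndarray:
    """Generator matrix of (d_0..d_{M-1}, g) with growth/death rate on g."""
    M = phen.m
    k = M / phen.lam  # per-state wake-up rate
    A = np.zeros((M + 1, M + 1))
    for i in range(M):
        A[i, i] = -k
        A[i + 1, i] = k
    A[M, M] = growth_rate
    return A


def integrate_single_round(
    phen: Phenotype,
    gamma: float,
    T: float,
    t_end: float | None = None,
    n_samples: int = 50,
) -> RoundTrajectory:
    """Propagate one round of the ``M``-step wake-up model exactly.

    The dynamics are a piecewise-constant linear system (kill rate ``γ``
    on ``[0, T]``, growth rate 1 on ``(T, t_end]``) and are propagated by
    the matrix exponential per phase, so the solution is exact to
    rounding.  Initial condition: all mass in the first dormant state.

    ``ln[g(t_end)/e^{t_end}]`` converges to ``ln f(T)`` with a residual
    decaying like ``e^{-(1 + M/λ) t_end}``; the default
    ``t_end = T + 10λ + 20`` keeps it below ~1e-9 and callers needing the
    asymptotic value should keep ``t_end ≳ T + 10λ + 10``.
    """
    if phen.lam <= 0:
        raise ValueError("integrate_single_round requires lam > 0")
    if t_end is None:
        t_end = T + 10.0 * phen.lam + 20.0
    if t_end <= T:
        raise ValueError(f"t_end ({t_end}) must exceed the antibiotic duration T ({T})")

    M = phen.m
    A_kill = _wakeup_generator(phen, -gamma)
    A_grow = _wakeup_generator(phen, 1.0)

    times = np.unique(np.concatenate([np.linspace(0.0, t_end, n_samples), [T, t_end]]))
    y0 = np.zeros(M + 1)
    y0[0] = 1.0
    y_T = expm(A_kill * T) @ y0 if T > 0 else y0

    d_out = np.empty((len(times), M))
    g_out = np.empty(len(times))
    for i, t in enumerate(times):
        if t <= T:
            y = expm(A_kill * t) @ y0
        else:
            y = expm(A_grow * (t - T)) @ y_T
        d_out[i] = np.maximum(y[:M], 0.0)
        g_out[i] = max(y[M], 0.0)

    log_rel_growth = float(np.log(g_out[-1]) - t_end)
    return RoundTrajectory(times=times, d=d_out, g=g_out, log_rel_growth=log_rel_growth)


def erlang_lag_pdf(l, M: int, lam: float):
    """Erlang lag-time density: ``M`` sequential exponential steps, mean ``lam``.

    Identical to a Gamma density with shape ``M`` and scale ``λ/M``; the
    mean is ``λ`` for every ``M`` while the variance shrinks as ``λ²/M``.
    """
    if int(M) != M or M < 1:
        raise ValueError(f"M must be an integer >= 1, got {M}")
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    l_arr = np.asarray(l, dtype=float)
    if np.any(l_arr < 0):
        raise ValueError("lag times must be >= 0")
    out = _gamma_dist.pdf(l_arr, a=M, scale=lam / M)
    return out.item() if np.isscalar(l) or l_arr.ndim == 0 else out
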