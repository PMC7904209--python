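"""Duration distributions q(T) and discretized lag-time distributions r(l).

Both kinds of distribution live on a common grid of half-open bins
``[nΔ, (n+1)Δ)`` with the left edge ``nΔ`` as the representative point.
Bin 0 of a lag-time distribution carries the delta-at-origin mass of the
optimal-distribution theory.  This module is also the fixture generator
for the test suite: every synthetic q(T) and r(l) used anywhere in the
repository is built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, stats

__all__ = [
    "QFamilySpec",
    "DurationDistribution",
    "DiscretizedLagDistribution",
    "ErlangMixture",
    "make_duration_distribution",
    "discretize_lag_distribution",
]

_SIMPLEX_TOL = 1e-9


def _check_simplex(w: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < -tol):
        raise ValueError("weights must be nonnegative")
    s = w.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 (got {s!r})")
    w = np.clip(w, 0.0, None)
    return w / w.sum()


@dataclass(frozen=True)
class DiscretizedLagDistribution:
    """Lag-time distribution r(l) binned with width ``delta``.

    ``weights[n]`` is the probability mass of ``[nΔ, (n+1)Δ)``;
    ``weights[0]`` holds any atom at the origin.
    """

    delta: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("bin width delta must be > 0")
        object.__setattr__(self, "weights", _check_simplex(self.weights))

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def lag_grid(self) -> np.ndarray:
        """Representative lag time of each bin (left edge nΔ)."""
        return np.arange(len(self.weights)) * self.delta

    def mean(self) -> float:
        return float(self.lag_grid @ self.weights)


@dataclass(frozen=True)
class DurationDistribution:
    """Antibiotic-duration distribution q(T) binned on ``[0, t_max)``."""

    family: str
    delta: float
    t_max: float
    weights: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("bin width delta must be > 0")
        n = int(round(self.t_max / self.delta))
        if abs(n * self.delta - self.t_max) > 1e-9 * max(1.0, self.t_max):
            raise ValueError("t_max must be an integer multiple of delta")
        if len(self.weights) != n:
            raise ValueError(f"expected {n} = t_max/delta weights, got {len(self.weights)}")
        object.__setattr__(self, "weights", _check_simplex(self.weights))

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def duration_grid(self) -> np.ndarray:
        """Representative duration of each bin (left edge mΔ)."""
        return np.arange(len(self.weights)) * self.delta

    def mean(self) -> float:
        return float(self.duration_grid @ self.weights)


@dataclass(frozen=True)
class QFamilySpec:
    """Named duration-distribution family plus binning parameters.

    Families and their ``params``:

    - ``delta``: point mass, ``T0``
    - ``normal``: ``mu``, ``sigma`` (truncated to ``[0, t_max]`` and renormalized)
    - ``exponential``: ``mean``
    - ``uniform``: ``a`` (support ``[0, a]``, ``a <= t_max``)
    - ``powerlaw_saturated``: ``alpha > 1``; density ∝ ``(T + Δ)^{-α}`` —
      the saturation constant equals the bin width
    - ``normal_mixture``: ``means``, ``sigmas``, ``weights`` sequences
    """

    family: str
    t_max: float
    delta: float
    params: dict = field(default_factory=dict)


def _bin_edges(t_max: float, delta: float) -> np.ndarray:
    n = int(round(t_max / delta))
    return np.arange(n + 1) * delta


def make_duration_distribution(spec: QFamilySpec) -> DurationDistribution:
    """Bin a named q(T) family on ``[0, t_max)``: ``q_m = CDF((m+1)Δ) - CDF(mΔ)``.

    Mass outside ``[0, t_max]`` is truncated and the weights renormalized.
    The ``delta`` family puts all mass in the (left-closed) bin containing
    ``T0``.
    """
    edges = _bin_edges(spec.t_max, spec.delta)
    n = len(edges) - 1
    fam = spec.family
    p = spec.params
    if fam == "delta":
        t0 = float(p["T0"])
        if not 0 <= t0 < spec.t_max:
            raise ValueError(f"T0 must lie in [0, t_max), got {t0}")
        w = np.zeros(n)
        w[int(np.floor(t0 / spec.delta + 1e-12))] = 1.0
    elif fam == "normal":
        w = np.diff(stats.norm.cdf(edges, loc=float(p["mu"]), scale=float(p["sigma"])))
    elif fam == "exponential":
        w = np.diff(stats.expon.cdf(edges, scale=float(p["mean"])))
    elif fam == "uniform":
        a = float(p["a"])
        if not 0 < a <= spec.t_max:
            raise ValueError(f"uniform support bound a must be in (0, t_max], got {a}")
        w = np.diff(np.clip(edges / a, 0.0, 1.0))
    elif fam == "powerlaw_saturated":
        alpha = float(p["alpha"])
        if alpha <= 1:
            raise ValueError(f"power-law exponent alpha must be > 1, got {alpha}")
        # antiderivative of (T + Δ)^{-α}
        prim = (edges + spec.delta) ** (1.0 - alpha) / (1.0 - alpha)
        w = np.diff(prim)
    elif fam == "normal_mixture":
        means = np.asarray(p["means"], dtype=float)
        sigmas = np.asarray(p["sigmas"], dtype=float)
        mix = np.asarray(p.get("weights", np.full(len(means), 1.0 / len(means))), dtype=float)
        if not (len(means) == len(sigmas) == len(mix)):
            raise ValueError("means, sigmas, weights must have equal length")
        mix = mix / mix.sum()
        w = np.zeros(n)
        for mu_i, sd_i, x_i in zip(means, sigmas, mix):
            w += x_i * np.diff(stats.norm.cdf(edges, loc=mu_i, scale=sd_i))
    else:
        raise ValueError(f"unknown duration family {fam!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("duration distribution has no mass on [0, t_max]")
    return DurationDistribution(
        family=fam, delta=spec.delta, t_max=spec.t_max, weights=w / total, params=dict(p)
    )


@dataclass(frozen=True)
class ErlangMixture:
    """Mixture of Erlang lag-time phenotypes: fractions on the simplex,
    one mean lag per component, common shape ``m``. A component with
    ``lam == 0`` is a point mass at the origin."""

    fractions: np.ndarray
    lams: np.ndarray
    m: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", _check_simplex(self.fractions))
        lams = np.asarray(self.lams, dtype=float)
        if np.any(lams < 0):
            raise ValueError("mean lags must be >= 0")
        if len(lams) != len(self.fractions):
            raise ValueError("fractions and lams must have equal length")
        object.__setattr__(self, "lams", lams)
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("Erlang shape m must be an integer >= 1")

    def cdf(self, l) -> np.ndarray:
        l = np.asarray(l, dtype=float)
        out = np.zeros_like(l)
        for x_i, lam_i in zip(self.fractions, self.lams):
            if lam_i <= 0:
                out += x_i * (l >= 0)
            else:
                out += x_i * stats.gamma.cdf(l, a=self.m, scale=lam_i / self.m)
        return out


def discretize_lag_distribution(
    density: Callable[[np.ndarray], np.ndarray] | ErlangMixture,
    delta: float,
    n: int,
) -> DiscretizedLagDistribution:
    """Bin a lag-time law into ``n`` bins of width ``delta`` on ``[0, nΔ)``.

    A callable is treated as a (possibly unnormalized) density and
    integrated per bin by quadrature; an :class:`ErlangMixture` is binned
    exactly from its CDF, with zero-lag components landing in bin 0.
    The result is renormalized on the covered range.
    """
    edges = np.arange(n + 1) * delta
    if isinstance(density, ErlangMixture):
        w = np.diff(density.cdf(edges))
        w[0] += density.cdf(0.0).item()  # atoms at the origin
    else:
        w = np.empty(n)
        for i in range(n):
            val, _ = integrate.quad(density, edges[i], edges[i + 1], limit=200)
            w[i] = val
        if np.any(w < -1e-12 * max(w.max(), 1.0)):
            raise ValueError("density integrates to negative mass on some bin")
        w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("lag distribution has no mass on [0, n*delta)")
    return DiscretizedLagDistribution(delta=delta, weights=w / total)
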