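"""Maximizers over lag-time strategies.

Four strategy spaces, nested from most to least constrained:

- a single exponential phenotype (``optimize_single_lag``,
  ``find_critical_p``, ``scan_optimal_lag``);
- two phenotypes with fractions on the simplex
  (``optimize_two_phenotype``, ``phase_classify``,
  ``find_bet_hedging_boundary``);
- mixtures of ``Np`` Erlang phenotypes (``optimize_erlang_mixture``);
- arbitrary binned lag-time distributions, solved globally through the
  KKT conditions of the concave program (``solve_optimal_distribution``,
  ``kkt_residuals``).

The discretized fitness F_d is a log of affine functions of the bin
weights and hence concave on the simplex, so the KKT point found by
``solve_optimal_distribution`` is the global optimum and upper-bounds
every parametric strategy above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .distributions import (
    DiscretizedLagDistribution,
    DurationDistribution,
    ErlangMixture,
    discretize_lag_distribution,
)
from .fitness import (
    FitnessValue,
    effective_bin_weights,
    fitness_discretized,
    fitness_single_distributed_t,
    fitness_single_fixed_t,
    fitness_two_phenotype,
    h_matrix,
)

__all__ = [
    "SingleLagOptimum",
    "TransitionScan",
    "TwoPhenotypeOptimum",
    "PhaseDiagram",
    "KKTSolution",
    "ErlangMixtureOptimum",
    "NoTransitionError",
    "optimize_single_lag",
    "find_critical_p",
    "scan_optimal_lag",
    "optimize_two_phenotype",
    "phase_classify",
    "find_bet_hedging_boundary",
    "solve_optimal_distribution",
    "kkt_residuals",
    "optimize_erlang_mixture",
]


class NoTransitionError(RuntimeError):
    """Raised when no critical point exists in the scanned parameter range."""


# ---------------------------------------------------------------------------
# single phenotype
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-12  # fitness tie at the boundary resolves to λ* = 0


def _single_fitness(lam: float, gamma: float, p: float, duration) -> float:
    if isinstance(duration, DurationDistribution):
        return fitness_single_distributed_t(lam, gamma, p, duration).total
    return fitness_single_fixed_t(lam, gamma, p, float(duration)).total


@dataclass(frozen=True)
class SingleLagOptimum:
    """Global single-phenotype optimum plus the pieces it was chosen from."""

    lam_star: float
    fitness: float
    boundary_fitness: float  # F at λ = 0
    interior_lam: float | None  # best interior local maximum, if any
    interior_fitness: float | None

    @property
    def has_interior_maximum(self) -> bool:
        return self.interior_lam is not None


def _interior_maxima(
    gamma: float, p: float, duration, lam_hi: float, n_grid: int
) -> list[tuple[float, float]]:
    """All interior local maxima of F(λ) on (0, lam_hi], refined locally.

    The grid is log-spaced in 1/λ (the natural axis of the problem: both
    the short-lag and long-lag branches are resolved), spanning
    1/λ ∈ [1/lam_hi, 1e3].
    """
    u = np.logspace(np.log10(1.0 / lam_hi), 3.0, n_grid)  # u = 1/λ, increasing
    lams = 1.0 / u[::-1]  # increasing λ from 1e-3 to lam_hi
    F = np.array([_single_fitness(l, gamma, p, duration) for l in lams])
    out: list[tuple[float, float]] = []
    idx = np.where((F[1:-1] > F[:-2]) & (F[1:-1] >= F[2:]))[0] + 1
    for i in idx:
        res = minimize_scalar(
            lambda L: -_single_fitness(L, gamma, p, duration),
            bracket=(lams[i - 1], lams[i], lams[i + 1]),
            method="brent",
            options={"xtol": 1e-10},
        )
        out.append((float(res.x), float(-res.fun)))
    return out


def optimize_single_lag(
    gamma: float,
    p: float,
    duration: float | DurationDistribution,
    lam_hi: float | None = None,
    n_grid: int = 400,
) -> SingleLagOptimum:
    """Globally maximize the single-phenotype fitness over λ ∈ {0} ∪ (0, lam_hi].

    The boundary value F(0) is compared against the best interior local
    maximum found by a dense 1/λ grid plus Brent refinement.  A tie
    (within 1e-12) resolves to λ* = 0. ``lam_hi`` defaults to three
    times the (maximal) antibiotic duration.
    """
    if lam_hi is None:
        t_ref = duration.t_max if isinstance(duration, DurationDistribution) else float(duration)
        lam_hi = 3.0 * max(t_ref, 1.0)
    f0 = _single_fitness(0.0, gamma, p, duration)
    maxima = _interior_maxima(gamma, p, duration, lam_hi, n_grid)
    if not maxima:
        return SingleLagOptimum(0.0, f0, f0, None, None)
    lam_i, f_i = max(maxima, key=lambda t: t[1])
    if f_i > f0 + _TIE_TOL:
        return SingleLagOptimum(lam_i, f_i, f0, lam_i, f_i)
    return SingleLagOptimum(0.0, f0, f0, lam_i, f_i)


def find_critical_p(
    gamma: float,
    duration: float | DurationDistribution,
    mode: str = "global",
    tol: float = 1e-3,
    lam_hi: float | None = None,
) -> float:
    """Critical application probability of the single-phenotype transition.

    ``mode="local"``: smallest p at which F(λ) develops an interior local
    maximum at finite λ (the saddle-node where the long-lag branch is
    born). ``mode="global"``: smallest p at which that interior maximum
    overtakes the λ = 0 boundary value — the discontinuous transition of
    λ*.  Found by bisection to ``tol``; raises :class:`NoTransitionError`
    if even p = 1 shows no transition.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")

    def indicator(p: float) -> bool:
        opt = optimize_single_lag(gamma, p, duration, lam_hi=lam_hi)
        if mode == "local":
            return opt.has_interior_maximum
        return opt.lam_star > 0

    if not indicator(1.0):
        raise NoTransitionError(
            f"no {mode} critical point in (0, 1] for gamma={gamma}, duration={duration}"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if indicator(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class TransitionScan:
    """λ*(p) over a severeness grid, with the detected discontinuity."""

    p_grid: np.ndarray
    lam_star: np.ndarray
    fitness: np.ndarray
    jump_size: float  # largest |Δλ*| between adjacent grid points
    jump_p: float  # left edge of the grid interval where it occurs


def scan_optimal_lag(
    gamma: float,
    p_grid: Sequence[float],
    duration: float | DurationDistribution,
    lam_hi: float | None = None,
    n_grid: int = 400,
) -> TransitionScan:
    """Optimal lag λ* along a grid of application probabilities."""
    p_grid = np.asarray(p_grid, dtype=float)
    lam = np.empty_like(p_grid)
    fit = np.empty_like(p_grid)
    for i, p in enumerate(p_grid):
        opt = optimize_single_lag(gamma, p, duration, lam_hi=lam_hi, n_grid=n_grid)
        lam[i] = opt.lam_star
        fit[i] = opt.fitness
    jumps = np.abs(np.diff(lam))
    j = int(np.argmax(jumps)) if len(jumps) else 0
    return TransitionScan(
        p_grid=p_grid,
        lam_star=lam,
        fitness=fit,
        jump_size=float(jumps[j]) if len(jumps) else 0.0,
        jump_p=float(p_grid[j]) if len(jumps) else float("nan"),
    )


# ---------------------------------------------------------------------------
# two phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPhenotypeOptimum:
    """Global two-phenotype optimum (λ_a <= λ_b, x = fraction with λ_b).

    ``x_eff`` is the population fraction carrying a non-negligible lag —
    the quantity whose phase diagram the theory draws; it deduplicates
    the degenerate reparametrizations (λ_a = λ_b, or x = 1 with λ_b = 0)
    of the same physical strategy.  ``local_optima`` lists distinct local
    maxima (x, λ_a, λ_b, F) seen across the multistart.
    """

    x: float
    lam_a: float
    lam_b: float
    fitness: float
    x_eff: float
    local_optima: tuple = ()


def _canonical(x: float, la: float, lb: float) -> tuple[float, float, float]:
    if la > lb:
        x, la, lb = 1.0 - x, lb, la
    return x, la, lb


def _effective_fraction(x: float, la: float, lb: float, lam_tol: float) -> float:
    xe = 0.0
    if la > lam_tol:
        xe += 1.0 - x
    if lb > lam_tol:
        xe += x
    return xe


def optimize_two_phenotype(
    gamma: float,
    p: float,
    T: float,
    lam_hi: float | None = None,
    lam_tol: float = 1e-2,
    extra_starts: int = 0,
    seed: int = 0,
) -> TwoPhenotypeOptimum:
    """Maximize the two-phenotype fitness over (x, λ_a, λ_b) by multistart.

    27 deterministic starts (x ∈ {0.02, 0.5, 0.98} × a 3×3 grid of lag
    pairs scaled to T), optionally ``extra_starts`` random ones, each
    refined with L-BFGS-B under box bounds; the single-phenotype optimum
    is always included as a candidate so the strategy nesting
    F_two >= F_single holds by construction.
    """
    if lam_hi is None:
        lam_hi = max(3.0 * T, 5.0)

    def neg(v: np.ndarray) -> float:
        return -fitness_two_phenotype(v[0], v[1], v[2], gamma, p, T).total

    la_grid = (0.0, min(1.0, 0.5 * max(T, 1.0)), max(T, 0.5))
    lb_grid = (0.5 * max(T, 1.0), max(T, 0.5), min(2.0 * max(T, 0.5), lam_hi))
    starts = [
        (x0, la0, lb0) for x0 in (0.02, 0.5, 0.98) for la0 in la_grid for lb0 in lb_grid
    ]
    if extra_starts:
        rng = np.random.default_rng(seed)
        starts += [
            (rng.uniform(), rng.uniform(0, lam_hi), rng.uniform(0, lam_hi))
            for _ in range(extra_starts)
        ]

    bounds = [(0.0, 1.0), (0.0, lam_hi), (0.0, lam_hi)]
    optima: list[tuple[float, float, float, float]] = []
    for s in starts:
        res = minimize(neg, np.asarray(s), method="L-BFGS-B", bounds=bounds)
        x, la, lb = _canonical(*res.x)
        optima.append((x, la, lb, float(-res.fun)))

    # single-phenotype boundary candidates
    single = optimize_single_lag(gamma, p, T, lam_hi=lam_hi)
    optima.append((0.0, single.lam_star, single.lam_star, single.fitness))

    best = max(optima, key=lambda t: t[3])
    # deduplicate local optima by strategy signature
    distinct: list[tuple[float, float, float, float]] = []
    for cand in sorted(optima, key=lambda t: -t[3]):
        if all(
            abs(cand[3] - d[3]) > 1e-8
            or abs(_effective_fraction(cand[0], cand[1], cand[2], lam_tol)
                   - _effective_fraction(d[0], d[1], d[2], lam_tol)) > 1e-3
            for d in distinct
        ):
            distinct.append(cand)
    x, la, lb, F = best
    return TwoPhenotypeOptimum(
        x=x,
        lam_a=la,
        lam_b=lb,
        fitness=F,
        x_eff=_effective_fraction(x, la, lb, lam_tol),
        local_optima=tuple(distinct),
    )


@dataclass(frozen=True)
class PhaseDiagram:
    """Classification of the (p, T) plane by the optimal non-zero-lag fraction."""

    p_grid: np.ndarray
    t_grid: np.ndarray
    x_star: np.ndarray  # shape (len(p_grid), len(t_grid)); effective fraction
    phase: np.ndarray  # "zero" | "mixed" | "one"


def phase_classify(
    gamma: float,
    p_grid: Sequence[float],
    t_grid: Sequence[float],
    x_tol: float = 1e-2,
    lam_tol: float = 1e-2,
) -> PhaseDiagram:
    """Phase diagram of the optimal strategy: all-fast (x* = 0), all-slow
    (x* = 1), or bet-hedging (0 < x* < 1), per (p, T) grid cell."""
    p_grid = np.asarray(p_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    xs = np.empty((len(p_grid), len(t_grid)))
    phase = np.empty(xs.shape, dtype=object)
    for i, p in enumerate(p_grid):
        for j, T in enumerate(t_grid):
            opt = optimize_two_phenotype(gamma, p, T, lam_tol=lam_tol)
            xs[i, j] = opt.x_eff
            phase[i, j] = (
                "zero" if opt.x_eff < x_tol else "one" if opt.x_eff > 1 - x_tol else "mixed"
            )
    return PhaseDiagram(p_grid=p_grid, t_grid=t_grid, x_star=xs, phase=phase)


def find_bet_hedging_boundary(
    gamma: float,
    p_grid: Sequence[float],
    t_grid: Sequence[float],
    x_tol: float = 1e-2,
) -> float:
    """The p separating the two qualitative responses of x* to increasing T.

    Below the boundary x*(T) departs from 0 upward (bet-hedging invades
    an all-fast population as T grows); above it x*(T) departs from 1
    downward.  Each p is classified by the effective fraction at the
    smallest T of ``t_grid``; the boundary is the midpoint of the grid
    interval where the classification flips. ``t_grid`` should start
    well inside the single-strategy region (small T).
    """
    p_grid = np.sort(np.asarray(p_grid, dtype=float))
    t_grid = np.sort(np.asarray(t_grid, dtype=float))

    def rises(p: float) -> bool:
        for T in t_grid:
            xe = optimize_two_phenotype(gamma, p, float(T)).x_eff
            if xe < x_tol:
                return True  # still (or first) pinned at x* = 0 -> departs upward
            if xe > 1 - x_tol:
                return False  # pinned at x* = 1 -> departs downward
            return xe < 0.5  # already mixed at the smallest T: nearest pole
        return True

    flags = [rises(p) for p in p_grid]
    if all(flags) or not any(flags):
        raise NoTransitionError("no qualitative change of x*(T) within the p grid")
    k = int(np.argmin(flags))  # first p classified as falling-from-1
    return float(0.5 * (p_grid[k - 1] + p_grid[k]))


# ---------------------------------------------------------------------------
# optimal lag-time distribution (KKT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KKTSolution:
    """Optimal binned lag-time distribution with its KKT certificate.

    ``multipliers[n] = μ_n = 1 - Σ_m w_m h_n^m / <h^m>`` must be ~0 on
    the support and >= 0 off it; ``kkt_residual`` is the largest
    violation of stationarity, dual feasibility or complementary
    slackness.
    """

    distribution: DiscretizedLagDistribution
    multipliers: np.ndarray
    fitness: float
    support: np.ndarray  # bin indices with weight > support_tol
    kkt_residual: float
    converged: bool
    n_iterations: int

    @property
    def weights(self) -> np.ndarray:
        return self.distribution.weights

    @property
    def alpha(self) -> float:
        """Mass of the delta at the origin (bin 0)."""
        return float(self.distribution.weights[0])


def _kkt_quantities(r: np.ndarray, H: np.ndarray, w: np.ndarray):
    hm = r @ H
    grad = H @ (w / hm)  # Σ_m w_m h_n^m / <h^m>; equals 1 - μ_n at the optimum
    return hm, grad


def kkt_residuals(
    r_weights: np.ndarray,
    q: DurationDistribution,
    gamma: float,
    p: float,
    support_tol: float = 1e-8,
) -> tuple[np.ndarray, float, float]:
    """Evaluate the KKT system at a candidate distribution.

    Returns ``(μ, stationarity violation, complementary-slackness
    violation)`` where μ_n = 1 - Σ_m w_m h_n^m / <h^m>, stationarity is
    ``max |μ_n|`` over the support plus any dual infeasibility
    ``max(0, -μ_n)`` off it, and slackness is ``max |μ_n r_n|``.
    """
    r = np.asarray(r_weights, dtype=float)
    H = h_matrix(len(r), gamma, q.delta)
    w = effective_bin_weights(q.weights, p)
    _, grad = _kkt_quantities(r, H, w)
    mu = 1.0 - grad
    on = r > support_tol
    stat = float(np.max(np.abs(mu[on]))) if on.any() else 0.0
    dual = float(np.max(-mu[~on], initial=0.0))
    cs = float(np.max(np.abs(mu * r)))
    return mu, max(stat, dual), cs


def solve_optimal_distribution(
    q: DurationDistribution,
    gamma: float,
    p: float,
    n_bins: int | None = None,
    support_tol: float = 1e-8,
    kkt_tol: float = 1e-6,
    grad_tol: float = 1e-10,
    max_warm_iter: int = 5000,
    max_outer: int = 60,
) -> KKTSolution:
    """Globally optimal binned lag-time distribution for a duration law q.

    F_d is concave on the simplex, so the program is convex; we maximize
    it and certify optimality through the KKT conditions rather than
    guessing the active set.  Two stages:

    1. multiplicative (exponentiated-gradient) updates
       ``r_n <- r_n Σ_m w_m h_n^m / <h^m>`` — simplex-preserving, they
       shrink off-support bins geometrically and localize the support;
    2. an active-set Newton polish of the equality-constrained problem
       on the surviving bins, re-adding any pruned bin whose multiplier
       turns negative, until the certificate holds to ``grad_tol`` on
       the support and ``kkt_tol`` everywhere.

    Raises ``RuntimeError`` with the residuals if the certificate cannot
    be satisfied.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    N = len(q) if n_bins is None else int(n_bins)
    if N < len(q):
        raise ValueError("n_bins must cover all q bins")
    qw = np.zeros(N)
    qw[: len(q)] = q.weights
    H = h_matrix(N, gamma, q.delta)
    w = effective_bin_weights(qw, p)

    r = np.full(N, 1.0 / N)
    n_iter = 0
    for _ in range(max_warm_iter):
        hm, grad = _kkt_quantities(r, H, w)
        n_iter += 1
        if np.max(np.abs(grad[r > support_tol] - 1.0), initial=0.0) < 1e-8:
            break
        r = r * grad
        r /= r.sum()

    active = r > 1e-12
    for outer in range(max_outer):
        idx = np.where(active)[0]
        rs = r[idx].copy()
        Hs = H[idx]
        polished = False
        for _ in range(80):
            hm = rs @ Hs
            g = Hs @ (w / hm)
            n_iter += 1
            if np.max(np.abs(g - 1.0)[rs > 0], initial=0.0) < grad_tol:
                polished = True
                break
            # equality-constrained Newton step: curvature Q = -Hess F_d
            Q = (Hs * (w / hm**2)) @ Hs.T
            ns = len(rs)
            A = np.zeros((ns + 1, ns + 1))
            A[:ns, :ns] = Q
            A[:ns, ns] = 1.0
            A[ns, :ns] = 1.0
            b = np.concatenate([g, [0.0]])
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            dr = sol[:ns]
            step = 1.0
            neg = dr < 0
            if neg.any():
                step = min(1.0, float(np.min(-rs[neg] / dr[neg])))
            rs = np.maximum(rs + step * dr, 0.0)
            rs /= rs.sum()
        r = np.zeros(N)
        r[idx] = rs
        dropped = bool(np.any(active & (r <= 0.0)))
        active = r > 0
        _, grad = _kkt_quantities(r, H, w)
        reinstate = (~active) & (grad > 1.0 + 1e-12)
        if reinstate.any():
            active |= reinstate
            r[reinstate] = support_tol
            r /= r.sum()
            continue
        if polished and not dropped:
            break

    mu, stat, cs = kkt_residuals(r, _pad_q(q, N), gamma, p, support_tol)
    residual = max(stat, cs)
    converged = residual < kkt_tol
    dist = DiscretizedLagDistribution(delta=q.delta, weights=r)
    fitness = fitness_discretized(r, qw, gamma, p, q.delta, _H=H).total
    sol = KKTSolution(
        distribution=dist,
        multipliers=mu,
        fitness=fitness,
        support=np.where(r > support_tol)[0],
        kkt_residual=residual,
        converged=converged,
        n_iterations=n_iter,
    )
    if not converged:
        raise RuntimeError(
            f"KKT certificate not satisfied: stationarity {stat:.3e}, "
            f"slackness {cs:.3e} (tolerance {kkt_tol:.1e}); "
            f"support {sol.support.tolist()}"
        )
    return sol


def _pad_q(q: DurationDistribution, n: int) -> DurationDistribution:
    if n == len(q):
        return q
    w = np.zeros(n)
    w[: len(q)] = q.weights
    return DurationDistribution(
        family=q.family, delta=q.delta, t_max=n * q.delta, weights=w, params=q.params
    )


# ---------------------------------------------------------------------------
# Erlang mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErlangMixtureOptimum:
    """Best mixture of Np Erlang phenotypes (common shape m) under q."""

    mixture: ErlangMixture
    fitness: float

    @property
    def fractions(self) -> np.ndarray:
        return self.mixture.fractions

    @property
    def lams(self) -> np.ndarray:
        return self.mixture.lams


def optimize_erlang_mixture(
    n_phenotypes: int,
    m_states: int,
    gamma: float,
    p: float,
    q: DurationDistribution,
    lam_hi: float | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> ErlangMixtureOptimum:
    """Maximize fitness over mixtures of ``n_phenotypes`` Erlang lag laws.

    The mixture is scored through the same bin convention as ``q`` (the
    Erlang components are binned exactly from their Gamma CDFs and fed
    to F_d) but on a grid extended well past ``t_max``, so long-lag
    tails pay their full delay cost instead of being truncated away.
    Because the optimal distribution's support never extends past
    ``t_max``, the mixture fitness is still bounded by the KKT optimum
    on the shared grid.  Fractions are parametrized by a softmax, mean
    lags are box-bounded; ``n_starts`` seeded random multistarts.
    """
    if n_phenotypes < 1 or m_states < 1:
        raise ValueError("n_phenotypes and m_states must be >= 1")
    if lam_hi is None:
        lam_hi = 1.5 * q.t_max
    # cover the mixture tail until the e^{-l} delay cost is negligible
    N = int(round(q.t_max / q.delta)) + int(round((3.0 * lam_hi + 40.0) / q.delta))
    qw = np.zeros(N)
    qw[: len(q)] = q.weights
    H = h_matrix(N, gamma, q.delta)
    Np = n_phenotypes

    def unpack(v: np.ndarray) -> ErlangMixture:
        if Np == 1:
            fr = np.array([1.0])
            lams = np.clip(v, 0.0, lam_hi)
        else:
            z = v[: Np - 1]
            e = np.exp(np.concatenate([z - z.max(initial=0.0), [-z.max(initial=0.0)]]))
            fr = e / e.sum()
            lams = np.clip(v[Np - 1 :], 0.0, lam_hi)
        return ErlangMixture(fractions=fr, lams=lams, m=m_states)

    def neg(v: np.ndarray) -> float:
        mix = unpack(v)
        r = discretize_lag_distribution(mix, q.delta, N)
        return -fitness_discretized(r.weights, qw, gamma, p, q.delta, _H=H).total

    rng = np.random.default_rng(seed)
    n_var = (Np - 1) + Np
    bounds = [(-8.0, 8.0)] * (Np - 1) + [(0.0, lam_hi)] * Np
    best_v, best_f = None, -np.inf
    for k in range(n_starts):
        v0 = np.concatenate(
            [rng.normal(0.0, 1.0, Np - 1), rng.uniform(0.0, q.t_max, Np)]
        )
        if k == 0:  # canonical start: one zero-lag component, others spread over q
            v0 = np.concatenate([np.zeros(Np - 1), np.linspace(0.0, q.mean() * 1.5, Np)])
        res = minimize(neg, v0, method="L-BFGS-B", bounds=bounds)
        if -res.fun > best_f:
            best_f, best_v = float(-res.fun), res.x
    mix = unpack(best_v)
    order = np.argsort(mix.lams)
    mix = ErlangMixture(
        fractions=mix.fractions[order], lams=mix.lams[order], m=m_states
    )
    return ErlangMixtureOptimum(mixture=mix, fitness=best_f)
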