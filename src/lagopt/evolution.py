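"""In-silico serial inoculation–dilution evolution of the lag time.

N phenotypes with lag times λ_i = iΔλ + 1e-6 compete over repeated
rounds.  Each round: antibiotic applied with probability p (for a
duration T, killing growing cells at rate γ); the culture is incubated
to t = τ, harvested, and diluted back to total mass 1 in proportion to
each type's share, with all cells dormant again.  Mutation acts at
division only (daughters of the growing state switch type), so the
within-round dynamics are linear and are propagated exactly.

Any type whose mass drops below the extinction threshold δ_ext —
checked when an antibiotic application ends and again after each
dilution — is truncated to zero, representing less than one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PassageConfig",
    "PassageState",
    "PassageTrajectory",
    "BistabilityResult",
    "PopulationCollapseError",
    "run_serial_passages",
    "run_random_mutation_passages",
    "population_average_lag",
    "detect_bistability",
]


class PopulationCollapseError(RuntimeError):
    """Every phenotype fell below the extinction threshold."""


@dataclass(frozen=True)
class PassageConfig:
    """Parameters of the serial-passage experiment.

    Defaults follow the fixed-duration study conditions: N = 200 lag
    types spaced by Δλ = 0.1 (λ_i = iΔλ + 1e-6; the offset keeps the
    wake-up rate 1/λ_i finite), incubation τ = 20 per round, antibiotic
    regime (p, γ = 1, T = 6).  Mutation couples types during growth
    only: ``nearest`` moves a daughter to an adjacent type at rate
    ``mutation_rate`` per division and side (boundary types mutate
    inward only), ``random`` to any other type at rate
    ``mutation_rate`` per division and target.  The extinction
    threshold δ_ext is the mass of a single cell when the diluted
    culture is ~1e9 cells.
    """

    p: float
    gamma: float = 1.0
    T: float = 6.0
    tau: float = 20.0
    n_types: int = 200
    dlam: float = 0.1
    lam_offset: float = 1e-6
    mutation_rule: str = "nearest"
    mutation_rate: float = 2e-3
    delta_ext: float = 1e-9
    rounds: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.tau <= self.T:
            raise ValueError(f"incubation time tau ({self.tau}) must exceed T ({self.T})")
        if self.mutation_rule not in ("nearest", "random"):
            raise ValueError("mutation_rule must be 'nearest' or 'random'")
        if self.mutation_rule == "random" and self.mutation_rate * self.n_types >= 1.0:
            raise ValueError("random mutation requires rate * n_types < 1")
        if self.delta_ext < 0 or self.gamma < 0 or self.T < 0:
            raise ValueError("gamma, T and delta_ext must be >= 0")

    @property
    def lam(self) -> np.ndarray:
        return np.arange(self.n_types) * self.dlam + self.lam_offset


@dataclass
class PassageState:
    """Dormant/growing masses per type at one point of the experiment."""

    d: np.ndarray
    g: np.ndarray
    round_index: int = 0


@dataclass
class PassageTrajectory:
    """Per-round readouts of one serial-passage run."""

    config: PassageConfig
    mean_lag: np.ndarray  # population-averaged λ after each dilution
    sd_lag: np.ndarray  # within-round standard deviation of λ
    applied: np.ndarray  # antibiotic flags (bool)
    final_state: PassageState


# --- exact propagation of the piecewise-linear dynamics --------------------


def _mutation_generator(cfg: PassageConfig) -> np.ndarray:
    """Symmetric mutation generator L acting on the growing subpopulations;
    columns sum to zero, so mutation redistributes divisions without
    changing the total growth."""
    N = cfg.n_types
    eps = cfg.mutation_rate
    L = np.zeros((N, N))
    if eps == 0:
        return L
    if cfg.mutation_rule == "nearest":
        i = np.arange(N - 1)
        L[i, i + 1] = eps
        L[i + 1, i] = eps
        deg = np.full(N, 2.0)
        deg[0] = deg[-1] = 1.0  # boundary types mutate inward only
        L[np.arange(N), np.arange(N)] = -eps * deg
    else:
        # total mutation probability eps per division, split uniformly over
        # the N-1 possible target types
        L[:] = eps / (N - 1)
        L[np.arange(N), np.arange(N)] = -eps
    return L


def _psi(x: np.ndarray) -> np.ndarray:
    """(1 - e^{-x}) / x, the stable kernel of the wake-up convolution."""
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0, -np.expm1(-xs) / xs)


class _PhasePropagator:
    """Exact flow over a fixed time span of d_i' = -d_i/λ_i,
    g' = (a I + L) g + diag(1/λ_i) d, built from the eigendecomposition
    of the symmetric growth generator (L = 0 and a = -γ in the kill
    phase).  Exactness removes any tolerance coupling with the
    closed-form growth factors."""

    def __init__(self, lam: np.ndarray, a: float, L: np.ndarray, t: float):
        k = 1.0 / lam
        A = a * np.eye(len(lam)) + L
        mu, V = np.linalg.eigh(A)
        self.V = V
        self.k = k
        self.ed = np.exp(-k * t)
        self.emu = np.exp(mu * t)
        x = (mu[:, None] + k[None, :]) * t
        phi = self.emu[:, None] * t * _psi(x)  # (e^{μt} - e^{-kt})/(μ + k)
        self.PM = phi * V.T  # maps the wake-up source d0*k to eigenmodes

    def __call__(self, d: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        modes = self.emu * (self.V.T @ g) + self.PM @ (d * self.k)
        return d * self.ed, np.maximum(self.V @ modes, 0.0)


def _truncate(d: np.ndarray, g: np.ndarray, threshold: float) -> None:
    dead = (d + g) < threshold
    d[dead] = 0.0
    g[dead] = 0.0


def population_average_lag(state: PassageState, lam: np.ndarray) -> float:
    """Mass-weighted mean lag ⟨λ⟩ = Σ λ_i (d_i + g_i) / Σ (d_i + g_i)."""
    tot = state.d + state.g
    z = tot.sum()
    if z <= 0:
        raise ValueError("population has zero total mass")
    return float(lam @ tot / z)


def run_serial_passages(config: PassageConfig) -> PassageTrajectory:
    """Run the inoculation–dilution experiment for ``config.rounds`` rounds.

    All stochasticity is the Bernoulli(p) antibiotic draw from a single
    seeded generator, so trajectories are bit-reproducible.  Starts from
    all mass dormant in the shortest-lag type.  Raises
    :class:`PopulationCollapseError` if every type goes extinct.
    """
    cfg = config
    lam = cfg.lam
    L = _mutation_generator(cfg)
    L0 = np.zeros_like(L)
    prop_kill = _PhasePropagator(lam, -cfg.gamma, L0, cfg.T) if cfg.T > 0 else None
    prop_after = _PhasePropagator(lam, 1.0, L, cfg.tau - cfg.T)
    prop_full = _PhasePropagator(lam, 1.0, L, cfg.tau)

    rng = np.random.default_rng(cfg.seed)
    d = np.zeros(cfg.n_types)
    d[0] = 1.0
    mean_lag = np.empty(cfg.rounds)
    sd_lag = np.empty(cfg.rounds)
    applied = np.empty(cfg.rounds, dtype=bool)

    for rnd in range(cfg.rounds):
        g = np.zeros(cfg.n_types)
        applied[rnd] = rng.random() < cfg.p
        if applied[rnd] and prop_kill is not None:
            d, g = prop_kill(d, g)
            _truncate(d, g, cfg.delta_ext)  # when the application ends
            if d.sum() + g.sum() <= 0:
                raise PopulationCollapseError(f"population extinct in round {rnd}")
            d, g = prop_after(d, g)
        else:
            d, g = prop_full(d, g)
        tot = d + g
        z = tot.sum()
        if z <= 0:
            raise PopulationCollapseError(f"population extinct in round {rnd}")
        frac = tot / z
        frac[frac < cfg.delta_ext] = 0.0  # after the dilution is completed
        z2 = frac.sum()
        if z2 <= 0:
            raise PopulationCollapseError(f"population extinct in round {rnd}")
        frac /= z2
        m = float(lam @ frac)
        mean_lag[rnd] = m
        sd_lag[rnd] = float(np.sqrt(max((lam - m) ** 2 @ frac, 0.0)))
        d = frac

    final = PassageState(d=d, g=np.zeros_like(d), round_index=cfg.rounds)
    return PassageTrajectory(
        config=cfg, mean_lag=mean_lag, sd_lag=sd_lag, applied=applied, final_state=final
    )


def run_random_mutation_passages(config: PassageConfig) -> PassageTrajectory:
    """Serial passages with the all-to-all mutation kernel (any type can
    mutate to any other at ``mutation_rate`` per division and target)."""
    return run_serial_passages(replace(config, mutation_rule="random"))


# --- readouts ---------------------------------------------------------------


@dataclass(frozen=True)
class BistabilityResult:
    """Occupancy of the short-lag and long-lag branches after burn-in."""

    low_fraction: float
    high_fraction: float
    n_switches: int
    boundary: float
    bistable: bool


def detect_bistability(
    trajectory: PassageTrajectory,
    burn_in: int = 500,
    boundary: float = 0.5,
    min_occupancy: float = 0.02,
) -> BistabilityResult:
    """Classify post-burn-in rounds into branches by a log-scale boundary
    on ⟨λ⟩ and count branch switches.  ``bistable`` requires both
    branches to hold at least ``min_occupancy`` of the rounds."""
    m = trajectory.mean_lag
    if len(m) <= burn_in:
        raise ValueError("trajectory shorter than burn_in")
    post = m[burn_in:]
    high = post > boundary
    switches = int(np.sum(high[1:] != high[:-1]))
    hi_frac = float(high.mean())
    lo_frac = 1.0 - hi_frac
    return BistabilityResult(
        low_fraction=lo_frac,
        high_fraction=hi_frac,
        n_switches=switches,
        boundary=boundary,
        bistable=min(lo_frac, hi_frac) >= min_occupancy,
    )
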