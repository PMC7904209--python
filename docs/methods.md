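# Methods

This note records the model, the numerical choices, and the open design
decisions behind `lagopt`, at the level of detail a maintainer or a
careful user needs. Empirical claims below are limited to what the test
suite and `scripts/acceptance.py` actually compute.

## Model and assumptions

Time is measured in units of the inverse growth rate; the proliferation
rate is 1. A round starts with a fully dormant unit population in fresh
medium. With probability *p* the medium carries a bactericidal antibiotic
for a duration *T* (fixed, or drawn from a distribution q(T) supported on
[0, T_max]). Dormant cells neither grow nor die and are fully tolerant;
growing cells die at rate γ while the antibiotic is present and grow at
rate 1 after it is removed. Wake-up is irreversible within a round: the
lag-time law r(l) is the first-passage-time distribution into the single
absorbing growing state. Bacteriostatic action, partial tolerance of
dormant cells, within-round nutrient depletion, and arithmetic-mean
(expected-population) fitness are all out of scope.

Fitness is the geometric-mean log growth per round relative to a
zero-lag antibiotic-free culture,
F = (1−p)·ln f(0) + p·E_q[ln f(T)], which is ≤ 0 by construction and
equals 0 only when the antibiotic has no effect and all mass wakes
instantly. Averaging ln f (not f) over the environment is what makes
hedging pay: a round that annihilates the population cannot be
compensated by good rounds, so strategies are judged by their typical,
not expected, growth.

## Closed forms and the exact ODE route

For the exponential (one-step) lag the growth factor has the closed form
implemented in `growth.log_growth_factor_exp`. Two numerical points:

- the factor (e^{−T/λ} − e^{−γT})/(γλ − 1) has a removable singularity
  at γλ = 1. We evaluate it as e^{−T/λ}·(T/λ)·ψ(x) with
  x = (γ − 1/λ)T and ψ(x) = −expm1(−x)/x whenever |x| < 0.5, which is
  exact through the singularity (ψ(0) = 1) with no tolerance switch;
  away from that window the direct difference is safe and the expm1 form
  would overflow, hence the branch at |x| = 0.5.
- the whole expression is assembled in log space (logaddexp over the two
  terms' logarithms), so extreme T/λ or γT degrade gracefully to −inf
  instead of underflowing mid-formula.

`growth.integrate_single_round` propagates the (M+1)-dimensional linear
system by matrix exponential per phase — exact to rounding, so closed
form vs ODE comparisons in the tests carry no integrator tolerance. The
finite-horizon readout ln[g(t_end)] − t_end approaches ln f(T) with a
residual decaying like e^{−(1+M/λ)t_end}; the default horizon
t_end = T + 10λ + 20 keeps it below ~1e−9.

The M-step model's Erlang lag law (shape M, mean λ for every M) is
delegated to the scipy Gamma distribution.

## Discretization conventions

Lag and duration distributions share half-open bins [nΔ, (n+1)Δ) with
the *left edge* as representative point — the binned fitness F_d uses
e^{−nΔ} and e^{γnΔ} exactly as its defining display, and a point mass
lands in the bin containing it. Left-endpoint binning makes F_d
first-order accurate in Δ: the measured gap between the continuum
functional and F_d halves when Δ halves (≈1.9e−3 at Δ = 0.01 for the
Erlang-vs-normal test case), which the suite asserts as an O(Δ)
convergence check.

Normal (and mixture-of-normal) duration families are truncated to
[0, T_max] and renormalized; how sub-zero mass should be treated is not
otherwise determined, and truncation keeps durations nonnegative without
distorting the shape on the support. The saturated power law is
q(T) ∝ (T + Δ)^{−α} with the saturation constant tied to the bin width,
integrated in closed form per bin.

One bookkeeping identity matters throughout: writing w_0 = (1−p) + p·q_0
and w_m = p·q_m (m ≥ 1), the fitness is F_d = Σ_m w_m ln⟨h^m⟩, because a
round without antibiotic and a round of zero duration contribute the
same logarithm. These w are also the weights of the KKT system; they sum
to 1, which fixes the simplex multiplier and yields the Euler identity
Σ_n r_n ∂F_d/∂r_n = 1 used as a consistency check.

## Optimizers

**Single λ.** F(λ) can have two competing branches, so the maximizer
compares the λ = 0 boundary value (the analytic limit −p(1+γ)T, or its
q-average −p(1+γ)Σ_m q_m·mΔ for distributed durations) with the best *interior* local
maximum found on a log-spaced grid in 1/λ (400 points spanning 1/λ ∈
[1/λ_hi, 1e3], λ_hi = 3× the maximal duration) refined by Brent. Ties
within 1e−12 resolve to λ* = 0 — a deterministic, conservative
convention at the transition point. `find_critical_p` bisects (to 1e−3)
the indicator "an interior maximum exists" (local mode — the saddle-node
where the long-lag branch is born) or "λ* > 0" (global mode — the
discontinuous transition).

**Two phenotypes.** 27 deterministic multistarts (3 fractions × 3×3 lag
pairs scaled to T) refined by L-BFGS-B under box bounds, with the
single-phenotype optimum always injected as a candidate so the strategy
nesting F_two ≥ F_single holds by construction. The strategy space is
invariant under (x, λ_a, λ_b) → (1−x, λ_b, λ_a), so results are
canonicalized to λ_a ≤ λ_b. Phase classification uses the *effective*
slow fraction (mass on phenotypes with λ above a 1e−2 tolerance), which
collapses the degenerate reparametrizations of a single-phenotype
strategy (λ_a = λ_b, or x = 1 with λ_b = 0) to a well-defined scalar.
The regime boundary in p (where x*(T) switches from rising-out-of-0 to
falling-from-1) classifies each p by the effective fraction at the
smallest T of the scan grid.

**KKT solver.** F_d is a positive combination of logs of affine
functions, hence concave on the simplex; the program is convex and the
KKT point is the global optimum. Rather than guessing the active set, we
(1) run multiplicative (exponentiated-gradient) updates
r_n ← r_n Σ_m w_m h_n^m/⟨h^m⟩ — simplex-preserving because the
r-average of the update factor is 1 — which localize the support, then
(2) polish with an equality-constrained Newton method on the surviving
bins (bordered system solved by least squares, step clipped at the
nonnegativity boundary), re-adding any pruned bin whose multiplier
μ_n = 1 − Σ_m w_m h_n^m/⟨h^m⟩ turns negative. Tolerances:
support_tol = 1e−8 (a bin counts as support), kkt_tol = 1e−6 (the
certificate), gradient stationarity 1e−10 on the support; in practice
the polish reaches ~1e−14. Non-convergence raises with the residuals
rather than returning a silent approximation. The active-set structure
of the certificate also carries the theory's structural statements,
which the suite verifies rather than proves: at most two support bins
for a fixed duration, an empty gap of at least one bin above the origin
atom, and no support beyond T_max even when the grid extends past it.

**Erlang mixtures.** Mixtures of Np Erlang phenotypes (common shape M;
λ_i = 0 encodes the origin atom) are scored through the same Δ-binned
fitness as the KKT solver but on a grid extended well beyond T_max.
Truncating the mixture at T_max (as the plain r_n normalization would)
erases the delay cost of long-lag tails and visibly biases the optimum
(a single exponential under fixed T drifted from λ* ≈ 3.8 to 8.6);
on the extended grid the continuum optimum is recovered to ~1% at
Δ = 0.1. Because the optimal distribution's support stays below T_max,
the KKT fitness still upper-bounds every mixture on the shared grid.
Fractions are parametrized by a softmax, lags box-bounded, 20 seeded
random multistarts by default.

## Serial-passage evolution simulator

N = 200 types with λ_i = iΔλ + 1e−6 (Δλ = 0.1; the offset keeps 1/λ_i
finite) compete under the study regime γ = 1, T = 6, incubation τ = 20.
Within a round the dynamics are linear: d_i′ = −d_i/λ_i, and the growing
block g′ = (aI + L)g + diag(1/λ_i)d with a = −γ (antibiotic phase,
mutation off — dormant cells and dying cells do not divide) or a = 1
(growth phase, mutation on). L is the symmetric mutation generator:
nearest-neighbor moves a daughter to an adjacent type at rate ε per
division and side (boundary types mutate inward only); the all-to-all
rule spreads a *total* per-division probability ε̃ uniformly over the
N − 1 targets. Columns of L sum to zero, so mutation redistributes
divisions without changing total growth.

Propagation is exact: the growth generator is symmetric, so each phase
is an eigendecomposition plus the wake-up convolution
(e^{μt} − e^{−kt})/(μ + k), evaluated with the same expm1-stable ψ
kernel as the closed form (removable singularities at μ = −k are
crossed analytically). This handles the stiff 1/λ_0 = 1e6 rate without
step-size control; the suite cross-checks one phase against a stiff
adaptive integrator and three full rounds against an independently
assembled 2N-dimensional matrix exponential.

After each antibiotic application ends, and again after each dilution,
any type with total mass below δ_ext is truncated to zero ("less than
one cell"); the post-truncation fractions are renormalized so every
round starts with unit mass. All stochasticity is the Bernoulli(p)
antibiotic draw from one seeded generator — trajectories are
bit-reproducible.

Two parameters are not determined by the study conditions and were
calibrated once, before the test suite was written, against the
documented phenomenology (evolution of ⟨λ⟩ on the 10³-round scale;
a short-lag/long-lag bistable window bracketing the analytic transition
p ≈ 0.25, monostable on both sides):

- nearest-neighbor mutation rate ε = 2e−3 per division and side;
- extinction threshold δ_ext = 1e−9, the mass of one cell when the
  diluted culture is of order 1e9 cells.

A coarser setting (ε = 1e−3, δ_ext = 1e−6) leaves the long-lag branch
unable to nucleate through the truncated mutation front within a few
thousand rounds and shifts the observable window to p ≈ 0.28–0.32; the
sensitivity is reported here rather than hidden. For the all-to-all
rule, the *total-rate* reading of ε̃ is forced by the observable
mutation load: at ε̃ = 1e−4 it puts the short-lag branch at
⟨λ⟩ ≈ 2e−2, whereas a per-target reading would bury it under a mutant
cloud with ⟨λ⟩ ≈ 3.6 and no short-lag branch at all.

The bistability readout classifies post-burn-in rounds by a boundary on
⟨λ⟩ (default 0.5, roughly the geometric midpoint of the two branches on
a log scale) and reports branch occupancies and switch counts; a
trajectory counts as bistable when both branches hold ≥ 2% of rounds.
The simulation's critical p is estimated as the 0.5-crossing of the
seed-averaged long-lag occupancy over a p grid — the point where the
branches are equally stable — which is robust to single transient
excursions that an "any seed ever visited both branches" rule would
over-count.

## What the synthetic conditions do and do not show

All inputs are model-generated; there is no empirical data path. The
duration families (fixed, normal, exponential, saturated power law,
two-normal mixture, uniform) are the study conditions themselves, so
passing tests show internal consistency of the theory and its numerics —
reduction chains between independent routes (closed form vs ODE vs
functional vs discretization), certified global optimality on the
simplex, and agreement between analytic optima and the evolution
simulation's fixed points. They do not show that real lag-time
distributions are optimal: laboratory populations face correlated
stresses, finite-population noise, physiological constraints on
achievable lag laws, and mutation spectra none of which are modelled
here. The zero-lag atom in particular is an idealization; biologically
it stands for "the shortest achievable lag".

## Known limitations

- Scoring mixtures and the KKT program share the left-endpoint binning
  bias O(Δ); comparisons across different Δ should use the continuum
  functional (`fitness_functional`), which is quadrature-based and
  slower.
- The KKT solver's cost is dominated by the warm multiplicative stage
  (dense N×N matvecs); N of a few hundred is comfortable, N ≫ 10³ is
  not the intended regime.
- `optimize_two_phenotype` is a multistart local method; the 27-start
  grid is calibrated to the γ ≈ 1 regime scanned here and may need
  densifying for extreme γ.
- The evolution simulator tracks deterministic mass fractions with an
  extinction cutoff; it has no demographic noise, so branch-switching
  statistics reflect environmental (antibiotic-draw) stochasticity only.
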