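import numpy as np
import pytest

from lagopt import QFamilySpec, make_duration_distribution, solve_optimal_distribution

# the four duration-distribution settings of the optimal-distribution study:
# Δ = 0.1, T_max = 10, p = 0.8, γ = 1
STUDY_DELTA = 0.1
STUDY_TMAX = 10.0
STUDY_P = 0.8
STUDY_GAMMA = 1.0

STUDY_Q_SPECS = {
    "normal": QFamilySpec("normal", STUDY_TMAX, STUDY_DELTA, {"mu": 5.0, "sigma": 1.5}),
    "exponential": QFamilySpec("exponential", STUDY_TMAX, STUDY_DELTA, {"mean": 5.0}),
    "powerlaw": QFamilySpec("powerlaw_saturated", STUDY_TMAX, STUDY_DELTA, {"alpha": 2.0}),
    "bimodal": QFamilySpec(
        "normal_mixture", STUDY_TMAX, STUDY_DELTA, {"means": [1.0, 5.0], "sigmas": [1.0, 1.0]}
    ),
}


@pytest.fixture(scope="session")
def study_durations():
    """The four binned q(T) of the optimal-distribution study."""
    return {k: make_duration_distribution(s) for k, s in STUDY_Q_SPECS.items()}


@pytest.fixture(scope="session")
def study_kkt_solutions(study_durations):
    """KKT-optimal lag distributions for the four study q(T); solved once."""
    return {
        k: solve_optimal_distribution(q, STUDY_GAMMA, STUDY_P)
        for k, q in study_durations.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
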