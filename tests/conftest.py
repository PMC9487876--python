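import numpy as np
import pytest

from thetagrow import (
    SimulationParams,
    StudyDesign,
    ThetaLogisticParams,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """A reduced two-group layout: 3+3 clones, 4 populations each,
    6 censuses — big enough to fit every candidate, small enough to be
    fast."""
    return StudyDesign(
        groups=("pre", "post"),
        clones_per_group={"pre": 3, "post": 3},
        populations_per_clone=4,
        initial_abundance=1,
        census_days=tuple(11 + 8 * i for i in range(6)),
    )


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(
        group_params={
            "post": ThetaLogisticParams(r=0.2, K=30.0, theta=0.8),
            "pre": ThetaLogisticParams(r=0.15, K=20.0, theta=0.8),
        },
        sigma_clone=0.05,
        sigma_pop=0.02,
        sigma_r_clone=0.02,
        sigma_resid=0.05,
        demographic_stochasticity=False,
        biomass_cv=0.1,
    )


@pytest.fixture(scope="session")
def small_study(small_design, small_params):
    """Simulated census table + latent truth for the small design."""
    census, truth = simulate_study(small_design, small_params, seed=11,
                                   return_truth=True)
    return census, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
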