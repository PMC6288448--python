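"""Shared fixtures: small, fast communities for unit tests.

Full-scale study-condition runs live in test_acceptance.py behind
session-scoped fixtures so they execute once.
"""

import pytest

from hgtsim.dynamics import MINUTES_PER_DAY, SimulationConfig
from hgtsim.experiments import ScenarioSpec, draw_mechanism_set


@pytest.fixture
def small_config() -> SimulationConfig:
    """An 8-species community over 2000 steps, cheap enough for unit tests."""
    return SimulationConfig(
        n_species=8,
        total_time=30.0 * MINUTES_PER_DAY,
        n_steps=2000,
        per_species_density=1e5,
        initial_fraction=1e-3,
    )


@pytest.fixture
def small_mechanisms(small_config):
    """All four mechanisms for the small community, rates boosted so that
    spread completes within the short test horizon."""
    gammas = {
        "conjugation": 2e-8,
        "transformation": 1e-10,
        "transduction": 1e-9,
        "vesicle": 1e-11,
    }
    return draw_mechanism_set(small_config.n_species, seed=11, gammas=gammas, n_modules=2)


@pytest.fixture
def small_scenario(small_config) -> ScenarioSpec:
    return ScenarioSpec(
        name="small",
        enabled=("conjugation",),
        config=small_config,
        base_seed=7,
        n_replicates=3,
    )
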