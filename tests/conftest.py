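"""Shared fixtures: calibrated potentials, topology and synthetic datasets.

Everything is generated programmatically; the expensive calibrated objects
are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from mminfer.model_systems import (
    alanine_dipeptide_topology,
    apply_basin_correction,
    make_prior_potential,
)
from mminfer.synthetic_data import corrupt_data, generate_data, make_observables


@pytest.fixture(scope="session")
def prior_potential():
    """Two-basin prior calibrated to delta_f = -7.5, barrier = 38 kJ/mol."""
    return make_prior_potential(-7.5, 38.0)


@pytest.fixture(scope="session")
def reference_potential(prior_potential):
    """Prior with the 15 kJ/mol basin-B correction (the 'true' ensemble)."""
    return apply_basin_correction(prior_potential, 15.0)


@pytest.fixture(scope="session")
def mild_potential():
    """Low-barrier variant that plain Monte Carlo can sample ergodically."""
    return make_prior_potential(-3.0, 8.0)


@pytest.fixture(scope="session")
def topology():
    return alanine_dipeptide_topology()


@pytest.fixture(scope="session")
def observables36(topology, prior_potential):
    return make_observables(36, topology, rng_seed=1, potential=prior_potential)


@pytest.fixture(scope="session")
def dataset36(reference_potential, observables36):
    """36 noise-free reference-ensemble averages."""
    return generate_data(reference_potential, observables36)


@pytest.fixture(scope="session")
def corrupted_dataset36(dataset36):
    """Same data with systematic errors on 20% of the points."""
    return corrupt_data(dataset36, 0.20, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
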