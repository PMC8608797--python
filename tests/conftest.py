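"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from braferk import (CascadeModel, RateConstants, build_cascade_network,
                     default_initial_concentrations)


def brute_force_rhs(network, constants, x):
    """Independent mass-action derivative: loop over reactions, accumulate
    fluxes term by term into a plain dict keyed by species name.

    Deliberately structured unlike the compiled implementation (no arrays,
    no stoichiometric matrix) so the two can cross-check each other.
    """
    conc = {name: float(v) for name, v in zip(network.species_names, x)}
    delta = {name: 0.0 for name in conc}
    for r in network.reactions:
        flux = float(constants[r.fwd_rate])
        for name in r.reactants:
            flux *= conc[name]
        if r.kind == "binding":
            flux -= float(constants[r.rev_rate]) * conc[r.products[0]]
        for name in r.reactants:
            delta[name] -= flux
        for name in r.products:
            delta[name] += flux
    return np.array([delta[name] for name in network.species_names])


def random_states(network, rng, n, scale=100.0):
    """Random nonnegative states spanning several orders of magnitude."""
    dim = network.n_species
    mags = rng.uniform(-3, 4, size=(n, dim))  # 1e-3 .. 1e4 nM
    states = 10.0 ** mags
    states[rng.random(size=(n, dim)) < 0.1] = 0.0  # sprinkle exact zeros
    return states


@pytest.fixture(scope="session")
def full_network():
    return build_cascade_network(True, True)


@pytest.fixture(scope="session")
def drugfree_network():
    return build_cascade_network(False, False)


@pytest.fixture(scope="session")
def constants():
    return RateConstants.defaults()


@pytest.fixture(scope="session")
def baseline_initial():
    return default_initial_concentrations()


@pytest.fixture(scope="session")
def model():
    """Session-wide cascade model at the baseline parameterisation."""
    return CascadeModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240913)
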