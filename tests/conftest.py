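"""Shared fixtures: small crossed designs and one medium-sized
simulated dataset with its (expensive) estimator fits, computed once
per session and reused by unit and acceptance tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mtmmirt as mt
from mtmmirt.model import ModelParameters
from mtmmirt.simulate import SimulationSpec, simulate_responses


@pytest.fixture(scope="session")
def crossed22():
    """2 traits x 2 methods, 3 items per cell (12 items).

    Three indicators per trait-method cell keep the item-level
    trait/method variance split well identified, which the
    estimator-agreement tests rely on.
    """
    design = mt.crossed_design(["t1", "t2"], ["m1", "m2"], items_per_cell=3)
    I = design.n_items
    params = ModelParameters(
        trait_loadings=np.full(I, 1.0),
        method_loadings=np.full(I, 1.0),
        intercepts=np.linspace(-1.0, 1.0, I),
        trait_correlation=np.array([[1.0, 0.4], [0.4, 1.0]]),
    )
    return SimulationSpec(design, params, n_persons=1000)


@pytest.fixture(scope="session")
def crossed22_data(crossed22):
    rng = np.random.default_rng(20210316)
    return simulate_responses(crossed22, rng)


@pytest.fixture(scope="session")
def quad_fit22(crossed22, crossed22_data):
    return mt.fit_quadrature(crossed22.design, crossed22_data,
                             points_per_dim=5)


@pytest.fixture(scope="session")
def mcll_fit22(crossed22, crossed22_data):
    from mtmmirt.mcll import fit_mcll
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mcll(crossed22.design, crossed22_data, chains=3,
                        iterations=1000, burn_in=1500, seed=7)


@pytest.fixture(scope="session")
def aip_fit22(crossed22, crossed22_data):
    from mtmmirt.aip import run_aip
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_aip(crossed22.design, crossed22_data, iterations=150,
                       burn_in=75, seed=7, points_per_dim=5)


@pytest.fixture()
def small_1d_2pl():
    """One trait, one method, 6 items; generating method loadings zero,
    so the data follow a plain unidimensional 2PL."""
    design = mt.crossed_design(["t"], ["m"], items_per_cell=6)
    params = ModelParameters(
        trait_loadings=np.full(6, 1.2),
        method_loadings=np.zeros(6),
        intercepts=np.linspace(-1.2, 1.2, 6),
        trait_correlation=np.eye(1),
    )
    return SimulationSpec(design, params, n_persons=1000)
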