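"""Shared fixtures: expensive objects are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import ahusce
from ahusce import survival
from ahusce.params import load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return ahusce.load_reference_life_table()


@pytest.fixture(scope="session")
def relapse_data():
    return survival.load_reference_relapse_data()


@pytest.fixture(scope="session")
def all_fits(relapse_data):
    return survival.fit_all(relapse_data)


@pytest.fixture(scope="session")
def lognormal_fit(all_fits):
    return survival.select_model(all_fits, policy="named_override", override="lognormal")


@pytest.fixture(scope="session")
def base_outcomes(params, life_table, lognormal_fit):
    """Deterministic base-case run shared across the suite."""
    return ahusce.run_model(params, life_table, lognormal_fit)


@pytest.fixture(scope="session")
def psa_small(params, life_table, lognormal_fit):
    """A modest seeded PSA shared by the uncertainty and acceptance tests."""
    from ahusce.psa import run_psa

    return run_psa(params, lognormal_fit, n=1500, seed=20240717 % (2**31), table=life_table)


@pytest.fixture(scope="session")
def scenario_table(params, life_table, all_fits):
    """The full published scenario suite, computed once."""
    from ahusce.scenarios import scenario_suite

    return scenario_suite(params, life_table, all_fits).set_index("scenario")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
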