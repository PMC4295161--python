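import random

import pytest

import spermsim as ss


@pytest.fixture
def params():
    return ss.default_parameters()


@pytest.fixture
def grid(params):
    g = ss.build_grid(params.geometry)
    g.set_domains(params.position_domain)
    return g


@pytest.fixture
def rng():
    return random.Random(42)


@pytest.fixture(scope="session")
def baseline_run():
    """One seeded 10-cycle baseline run with full event logging, shared by
    the analytics/rules/property tests."""
    return ss.run(hours=2100, seed=1)


@pytest.fixture(scope="session")
def audited_run():
    """A short run with the occupancy/capacity audit executed every hour."""
    return ss.run(hours=450, seed=7, audit_every=1, record_moves=True)
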