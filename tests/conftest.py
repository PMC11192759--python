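import pytest

from netavatar.conditioning import build_avatar
from netavatar.engine import SimulationConfig
from netavatar.fixtures import (
    FixtureSpec,
    make_drug_panel,
    make_pathway_map,
    make_toy_network,
)
from netavatar.pharmacology import bioactivity_records_from_frame, build_target_profiles


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def toy_network(default_spec):
    net, meta = make_toy_network(default_spec)
    return net, meta


@pytest.fixture(scope="session")
def avatar(toy_network):
    """Untouched avatar of the default fixture network (no omics applied)."""
    net, _ = toy_network
    return build_avatar(net, None)


@pytest.fixture(scope="session")
def profiles(default_spec):
    records = bioactivity_records_from_frame(make_drug_panel(default_spec))
    return build_target_profiles(records, make_pathway_map(default_spec))


@pytest.fixture()
def fast_config():
    """Small but statistically meaningful ensemble for screen tests."""
    return SimulationConfig(n_replicates=30, rng_seed=11)
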