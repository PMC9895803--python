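import dataclasses

import pytest

from seedpurge.capsdesign import caps_fixture, load_enzymes
from seedpurge.simdata import SimConfig, make_gene_fixture, simulate_dataset


@pytest.fixture(scope="session")
def gene_fixture():
    return make_gene_fixture()


@pytest.fixture(scope="session")
def cfr10i():
    return load_enzymes()["Cfr10I"]


@pytest.fixture(scope="session")
def caps_pair():
    return caps_fixture()


@pytest.fixture()
def clean_config():
    """Study design with no sequencing error and no green carriers."""
    return dataclasses.replace(SimConfig(), error_rate=0.0, carrier_freq=0.0)


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimConfig(rng_seed=11))
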