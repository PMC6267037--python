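import pytest
from hypothesis import settings

import bhlhscan as bh
from bhlhscan.simulate import FamilySpec, generate_family

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def seed_block():
    return bh.load_seed_alignment()


@pytest.fixture(scope="session")
def profile(seed_block):
    return bh.build_consensus(seed_block)


@pytest.fixture(scope="session")
def scanner(seed_block):
    return bh.ConsensusDomainScanner().fit(seed_block)


@pytest.fixture(scope="session")
def clean_family():
    """A noise-free 60-gene family shared across read-only tests."""
    return generate_family(FamilySpec(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def clean_hits(clean_family, scanner):
    return scanner.predict(clean_family.proteins)
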