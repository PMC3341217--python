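import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import attkit as ak

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def random_att_site(rng: np.random.Generator, name: str, length: int) -> ak.AttSiteSpec:
    """A random att site with a GT core at a random interior offset."""
    core_offset = int(rng.integers(0, length - 1))
    seq = list(random_dna(rng, length))
    seq[core_offset : core_offset + 2] = "GT"
    return ak.AttSiteSpec(name, "".join(seq), core_offset)


@pytest.fixture(scope="session")
def unexcised():
    return ak.make_fixture_construct("unexcised")


@pytest.fixture(scope="session")
def excised():
    return ak.make_fixture_construct("excised")


@pytest.fixture(scope="session")
def recombinase():
    return ak.make_fixture_construct("recombinase")


@pytest.fixture()
def rng():
    return np.random.default_rng(1729)
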