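import pytest

from bcrsim.germline import build_locus
from bcrsim.recombination import simulate_repertoire
from bcrsim.synthetic import make_synthetic_reference


@pytest.fixture(scope="session")
def ref():
    """Synthetic germline + reference bundle shared across the suite."""
    return make_synthetic_reference(seed=1)


@pytest.fixture(scope="session")
def bundle(ref):
    return ref.bundle


@pytest.fixture(scope="session")
def locus(ref):
    return build_locus(ref.v, ref.d, ref.j, heterozygosity="all", rng_seed=0)


@pytest.fixture(scope="session")
def by_name(locus):
    return locus.by_name()


@pytest.fixture(scope="session")
def mutated_repertoire(locus, bundle):
    """1,000 SHM-on rearrangements used by several invariant tests."""
    return list(simulate_repertoire(locus, bundle, 1000, shm_on=True, rng_seed=5))
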