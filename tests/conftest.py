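import pytest

from dcjmetric.fixtures import (make_path7_fixture, make_tightness_family,
                                random_genome_pair)
from dcjmetric.graph import build_adjacency_graph


@pytest.fixture(scope="session")
def tightness_family_200():
    return make_tightness_family(200)


@pytest.fixture(scope="session")
def path7_component():
    a, b = make_path7_fixture()
    return build_adjacency_graph(a, b).components[0]


# mixed-size seeded pairs used by the exact-search checks; shared between
# the unit and acceptance suites so repeated searches hit the memo
TINY_PAIR_CONFIGS = [(2, 1, 1), (1, 1, 2), (2, 1, 2), (0, 1, 1), (1, 1, 1)]


def tiny_pair(seed: int):
    n_common, n_unique, chroms = TINY_PAIR_CONFIGS[seed % len(
        TINY_PAIR_CONFIGS)]
    return random_genome_pair(n_common, n_unique, chromosomes=chroms,
                              seed=9000 + seed)


@pytest.fixture(scope="session")
def tiny_pairs_50():
    return [tiny_pair(s) for s in range(50)]
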