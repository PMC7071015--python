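"""Shared fixtures: the worked-example macrocycle and a synthetic truth."""

import numpy as np
import pytest

from cyclomimic.peptide import build_topology, parse_design
from cyclomimic.synthetic import make_ground_truth


@pytest.fixture(scope="session")
def seq11():
    """The worked-example design: 9-residue epitope + Pro-Gly linker."""
    return parse_design("HYWSENLFQ", "PG", True)


@pytest.fixture(scope="session")
def topo11(seq11):
    return build_topology(seq11)


@pytest.fixture(scope="session")
def truth11(seq11):
    """Deterministic synthetic ground-truth conformation of the 11-mer."""
    return make_ground_truth(seq11, seed=5)


@pytest.fixture(scope="session")
def toy4():
    """4-residue toy macrocycle for exhaustive-scan comparisons."""
    return build_topology(parse_design("AGAG", "", True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
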