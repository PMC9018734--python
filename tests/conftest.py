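import numpy as np
import pytest

from wtpe.simulate import (
    make_deletion_scenario,
    make_single_edit_scenario,
    make_translocation_scenario,
)


@pytest.fixture(scope="session")
def deletion_scenario():
    """C1 deletion toy: 600-nt locus, cuts at 150/450, 6-nt edit."""
    return make_deletion_scenario(seed=1)


@pytest.fixture(scope="session")
def deletion_scenario_c2():
    return make_deletion_scenario(seed=2, design_class="C2")


@pytest.fixture(scope="session")
def single_edit_scenario():
    """HA-free single-site toy with a 6-nt edit on a 240-nt locus."""
    return make_single_edit_scenario(seed=3, edit_seq="GATATC", ha_len=0)


@pytest.fixture(scope="session")
def translocation_scenario():
    return make_translocation_scenario(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
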