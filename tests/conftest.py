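import numpy as np
import pytest

from nstarkit.forcefield import (AB42_SEQUENCE, build_topology,
                                 default_forcefield, extended_conformation)


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def small_topology(ff):
    # 12-residue amyloidogenic core fragment; every bead class represented
    return build_topology("KLVFFAEDVGSN", ff)


@pytest.fixture(scope="session")
def ab42_topology(ff):
    return build_topology(AB42_SEQUENCE, ff)


@pytest.fixture
def small_conformation(small_topology):
    rng = np.random.default_rng(42)
    return extended_conformation(small_topology, jitter=0.25, rng=rng)
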