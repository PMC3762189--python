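import numpy as np
import pytest

from branchkin import Conditions, build_network, simulate


@pytest.fixture(scope="session")
def branching_network():
    return build_network("branching")


@pytest.fixture(scope="session")
def set3_conditions():
    """Activation-assay conditions: 3 uM actin, 50 nM Arp2/3, VCA ladder."""
    return Conditions(actin_monomer=3.0, arp23=0.05, gst_vca_monomeric=0.1,
                      t_end=1500.0)


@pytest.fixture(scope="session")
def set4_conditions():
    """Synergy-assay conditions: 3 uM actin, 20 nM Arp2/3, 100 nM GST-VCA."""
    return Conditions(actin_monomer=3.0, arp23=0.02, gst_vca_monomeric=0.1,
                      t_end=2000.0)


@pytest.fixture(scope="session")
def recycling_run(set4_conditions):
    """One recycling-variant run at zero cortactin, to equilibrium."""
    return simulate(build_network("recycling"), set4_conditions)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
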