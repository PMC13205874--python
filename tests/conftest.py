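import numpy as np
import pytest

from phasediv.simulate import SimulationConfig, simulate_diploid
from phasediv.synteny import chain_anchors, classify_regions, find_anchors


@pytest.fixture(scope="session")
def sim1():
    """Default-configuration dataset, seed 1 (the canonical run)."""
    return simulate_diploid(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def calls1(sim1):
    """Region calls from the anchor-based comparison of the seed-1 dataset."""
    anchors = find_anchors(sim1.hap1, sim1.hap2)
    return classify_regions(chain_anchors(anchors), sim1.hap1, sim1.hap2)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
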