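import numpy as np
import pytest

from satrna import satsim
from satrna.tandem_mapper import SatelliteConsensus


@pytest.fixture(scope="session")
def monomer_360() -> str:
    return satsim.generate_monomer(360, gc_fraction=0.45, seed=11)


@pytest.fixture(scope="session")
def consensus_360(monomer_360) -> SatelliteConsensus:
    return SatelliteConsensus("TCAST1B", monomer_360)


@pytest.fixture(scope="session")
def subfamily_pair(monomer_360):
    """Two diverged subfamily consensuses sharing ~90% identity."""
    variant, _ = satsim.derive_subfamily(monomer_360, divergence=0.10, seed=5)
    return SatelliteConsensus("TCAST1A", variant), SatelliteConsensus("TCAST1B", monomer_360)


def binomial_3sd(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1 - p) / n)
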