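import warnings

import numpy as np
import pytest

from loopscan import synthetic
from loopscan.motifs import annotate_mcf
from loopscan.tripartite import derive_elements


@pytest.fixture(scope="session")
def carrier():
    """The synthetic carrier-like fixture (sequence + gapped alignment)."""
    return synthetic.aac_like()


@pytest.fixture(scope="session")
def carrier_map(carrier):
    return carrier.triplet_map()


@pytest.fixture(scope="session")
def carrier_hits(carrier, carrier_map):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return annotate_mcf(carrier.sequence, carrier_map)


@pytest.fixture(scope="session")
def carrier_elements(carrier_map, carrier_hits):
    return derive_elements(carrier_map, carrier_hits)


@pytest.fixture(scope="session")
def tripartite_truth():
    """A generator-made tripartite sequence with planted motifs."""
    return synthetic.gen_tripartite_sequence(synthetic.SequenceScenario(seed=424242))


@pytest.fixture
def rng():
    return np.random.default_rng(20220917)
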