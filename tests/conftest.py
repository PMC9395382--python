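import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

# Fitted (K_b / M^-1, site size / bp) pairs for the six dyes, used as
# ground truth for generator -> fitter round trips.
DYE_BINDING_PARAMS = {
    "PY+": (1.0e4, 4.4),
    "PY2+(C4)": (14.1e4, 4.0),
    "BT+": (3.5e4, 2.5),
    "BT2+(NEt2)": (12.1e4, 2.5),
    "4QL+": (7.0e4, 2.8),
    "4QL2+": (24.5e4, 2.1),
}

STRAND_1 = "CGCGGCGTACAGTGATCTACCATGCCCTGG"
STRAND_2 = "CCAGGGCATGGTAGATCACTGTACGCCGCG"  # reverse complement of STRAND_1


@pytest.fixture(scope="session")
def duplex_strands():
    return STRAND_1, STRAND_2


@pytest.fixture
def rng():
    return np.random.default_rng(42)
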