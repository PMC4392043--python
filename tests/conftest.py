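import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from prescan.motif_dictionary import PPM, MotifRecord


def random_ppm(rng, motif_id="m", width=None, concentration=1.0):
    width = width or int(rng.integers(4, 12))
    probs = rng.dirichlet(np.full(4, concentration), size=width).T
    return PPM(motif_id, probs)


def certain_ppm(motif_id, consensus, p=0.97):
    """PPM whose columns put probability p on the consensus base."""
    cols = []
    for base in consensus:
        col = np.full(4, (1 - p) / 3)
        col["ACGT".index(base)] = p
        cols.append(col)
    return PPM(motif_id, np.array(cols).T)


def record(motif_id, consensus, p=0.97, **kwargs):
    return MotifRecord(motif_id, certain_ppm(motif_id, consensus, p), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
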