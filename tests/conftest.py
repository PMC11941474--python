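import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from spacerforge import GenomeSequence, generate_genome, toy_kit


@pytest.fixture(scope="session")
def kit():
    return toy_kit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250923)


def random_spacer(rng, length=34, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def hi_gc_genome():
    """100-kb high-GC genome shared by the slower scans."""
    return generate_genome(100_000, gc=0.72, seed=11, record_id="chr")
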