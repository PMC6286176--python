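import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from methseek.core import ContigTable, GenomicWindow


@pytest.fixture
def contigs() -> ContigTable:
    return ContigTable([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def window() -> GenomicWindow:
    return GenomicWindow("chr1", 1000, 1500, "tx1", "promoter", "+")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
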