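import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cinscope.genome import BinTrack, make_genome, toy_genome
from cinscope.simulate import simulate_bin_track


@pytest.fixture(scope="session")
def toy30():
    """22-autosome toy genome at 1/30 human scale (~200 bins of 500 kb)."""
    return toy_genome(30)


@pytest.fixture(scope="session")
def toy5():
    """Bulk-sized toy genome at 1/5 human scale (~1,150 bins)."""
    return toy_genome(5)


@pytest.fixture(scope="session")
def track30(toy30):
    return simulate_bin_track(toy30, seed=11)


@pytest.fixture(scope="session")
def flat_track30(toy30):
    """Featureless track: constant GC, full mappability, no blacklist."""
    return BinTrack.uniform(toy30.n_bins)


@pytest.fixture()
def tiny_genome():
    """One 6 Mb chromosome, 12 bins, for hand-checkable cases."""
    return make_genome([6_000_000], bin_size=500_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
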