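import numpy as np
import pytest

from matingkit.io import ProgenyArray
from matingkit.mating import PollenPool


def make_array(offspring, maternal=None, loci=None, family="F01", pop="pop"):
    """Build a ProgenyArray from nested lists of (a1, a2) pairs."""
    off = np.asarray(offspring, dtype=np.int64)
    locus_names = loci or [f"L{j + 1}" for j in range(off.shape[1])]
    return ProgenyArray(
        family_id=family,
        population_id=pop,
        locus_names=locus_names,
        offspring=off,
        maternal=None if maternal is None else np.asarray(maternal, dtype=np.int64),
    )


def make_pollen(freqs):
    """PollenPool from a list of {allele: freq} dicts."""
    return PollenPool([f"L{j + 1}" for j in range(len(freqs))], [dict(f) for f in freqs])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
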