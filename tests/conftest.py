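import numpy as np
import pandas as pd
import pytest

from uradna import simulate
from uradna.tracks import BinnedTrack


@pytest.fixture(scope="session")
def small_genome():
    """200 kb two-chromosome genome, 2% hard-masked, fixed seed."""
    return simulate.generate_genome({"chrA": 120_000, "chrB": 80_000},
                                    gc_fraction=0.45, hardmask_fraction=0.02,
                                    seed=101)


@pytest.fixture(scope="session")
def segmentation(small_genome):
    return simulate.make_segmentation(small_genome.chrom_sizes,
                                      ["L0", "L1", "L2"], seg_len=20_000,
                                      seed=102)


def make_track(chrom, values, bin_size=100, units="ratio", start=0):
    starts = start + bin_size * np.arange(len(values))
    df = pd.DataFrame({"chrom": chrom, "start": starts,
                       "end": starts + bin_size, "value": values})
    return BinnedTrack(df, units=units)


@pytest.fixture
def uniform_track():
    return make_track("chrA", np.ones(50))
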