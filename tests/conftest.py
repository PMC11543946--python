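import numpy as np
import pandas as pd
import pytest

from restquant import region_stats as rs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome():
    return rs.Genome({"chr1": 1_000_000, "chr2": 500_000})


def regions(*tuples) -> rs.RegionSet:
    """Shorthand: regions(("chr1", 0, 100), ...) with optional summit."""
    rows = [t for t in tuples]
    ncol = len(rows[0])
    cols = ["chrom", "start", "end", "summit"][:ncol]
    return rs.RegionSet(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def make_regions():
    return regions
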