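import numpy as np
import pytest

from dnadda.sequence_walk import GenomicBins, make_bins


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simple_bins(n: int, bin_size: int = 100, chrom: str = "chrT") -> GenomicBins:
    """Exact-tiling bins for matrix-level tests (no partial trailing bin)."""
    return make_bins({chrom: n * bin_size}, bin_size)[chrom]


@pytest.fixture
def bins10() -> GenomicBins:
    return simple_bins(10)
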