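import numpy as np
import pytest

from exoncnv.depth_ratio import RatioSeries
from exoncnv.regions import GenomicInterval, ReferenceSequence


def make_ratio_series(values) -> RatioSeries:
    """Wrap a plain array of ratios in consecutive dummy intervals."""
    records = tuple(
        (GenomicInterval("chr1", i * 100, i * 100 + 50), float(v))
        for i, v in enumerate(values)
    )
    return RatioSeries(records, n_excluded=0, scale_factor=1.0)


@pytest.fixture
def toy_ref() -> ReferenceSequence:
    return ReferenceSequence(
        {
            "chrA": "ACGT" * 250,          # GC 0.5, length 1000
            "chrG": "G" * 100,             # GC 1.0
            "chrN": "N" * 50 + "A" * 50,   # half undefined
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
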