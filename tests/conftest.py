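import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from p53response.intervals import GenomicInterval, Peak, PeakSet


def make_peak(name, chrom="chr1", start=0, end=100, summit=None,
              chip=200, inp=50, libsize=1_000_000, enrichment=None):
    p = Peak(
        interval=GenomicInterval(chrom, start, end, name=name),
        summit_offset=(end - start) // 2 if summit is None else summit - start,
        chip_count=chip, input_count=inp,
        chip_libsize=libsize, input_libsize=libsize,
    )
    p.enrichment = enrichment
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def simple_peaks():
    return PeakSet(
        [make_peak(f"p{i}", start=i * 1000, end=i * 1000 + 200, enrichment=float(i))
         for i in range(10)],
        label="test",
    )
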