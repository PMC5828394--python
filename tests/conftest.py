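import numpy as np
import pytest
from hypothesis import settings

from ernascope.io_formats import Element, Gene, GenomeAnnotation, SignalTrack

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_track(entries, chrom_lengths=None):
    """Build a SignalTrack from (chrom, strand, pos, count) tuples."""
    t = SignalTrack(chrom_lengths)
    for chrom, strand, pos, count in entries:
        t.add(chrom, strand, pos, count)
    return t


@pytest.fixture
def simple_annotation():
    """One + gene at 1000-5000 and one - gene at 20000-24000 on chr2L."""
    return GenomeAnnotation(
        genes=[
            Gene("gA", "chr2L", 1000, 5000, "+"),
            Gene("gB", "chr2L", 20000, 24000, "-"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


def element(start, end, chrom="chr2L", **kw):
    return Element(chrom, start, end, **kw)
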