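import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from poisedpol.annotation import GeneModel
from poisedpol.coverage import RPM, CoverageTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def plus_gene():
    return GeneModel(gene_id="gp", chrom="chr1", start=0, end=1000, strand="+")


@pytest.fixture
def minus_gene():
    return GeneModel(gene_id="gm", chrom="chr1", start=0, end=1000, strand="-")


def make_track(values, chrom="chr1", normalization="raw"):
    return CoverageTrack(values={chrom: np.asarray(values, dtype=float)},
                         normalization=normalization)


@pytest.fixture
def uniform_track():
    def _make(value=2.0, length=2000, chrom="chr1", normalization=RPM):
        return make_track(np.full(length, value), chrom, normalization)
    return _make
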