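import numpy as np
import pytest

from equase.haplotypes import Haplotype, HetLocus
from equase.pileup import LocusTally


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_haplotype():
    return Haplotype(
        sample_id="s1",
        tissue="liver",
        block_id="b1",
        loci=(
            HetLocus("chr1", 100, "A", "G"),
            HetLocus("chr1", 250, "C", "T"),
        ),
    )


def make_tally(chrom, pos, ref, **counts):
    base = {b: 0 for b in "ACGT"}
    base.update(counts)
    return LocusTally(chrom=chrom, pos=pos, ref=ref, counts=base)


@pytest.fixture
def tally_factory():
    return make_tally
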