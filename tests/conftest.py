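import numpy as np
import pytest

from mebs.io_formats import AlignedRead, Genome, ORIGINAL_TOP


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genome():
    return Genome({"s1": "ACGTACGTAC", "s2": "NNACGCGTNN"})


def make_read(
    seq,
    start=0,
    scaffold="s1",
    read_id="r1",
    conv=ORIGINAL_TOP,
    cigar=None,
    strand="+",
    unique=True,
):
    """Convenience constructor for a fully-matching aligned read."""
    return AlignedRead(
        read_id=read_id,
        scaffold=scaffold,
        start=start,
        strand=strand,
        seq=seq,
        quals=[40] * len(seq),
        cigar=cigar or [("M", len(seq))],
        conversion_strand=conv,
        mate_id=read_id,
        unique=unique,
    )
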