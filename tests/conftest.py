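import numpy as np
import pytest

from pepsieve import fixtures
from pepsieve.fasta_db import Locus, SeqRecord, Source


@pytest.fixture
def rng():
    return np.random.default_rng(20210917)


@pytest.fixture
def sim_config():
    return fixtures.SimConfig(seed=11)


def make_record(rec_id, seq, source=Source.SORFS_ORG, locus=None, **kw):
    return SeqRecord(id=rec_id, description=rec_id, sequence=seq,
                     source=source, locus=locus, **kw)


def make_locus(chrom="chr1", strand="+", blocks=((0, 30),)):
    return Locus(chrom=chrom, strand=strand, blocks=tuple(blocks))


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
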