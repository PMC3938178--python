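import numpy as np
import pytest
from hypothesis import settings

from methylvar.alignments_io import BisRead

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def mk_read(seq, start=0, quals=30, bs="OT", chrom="c1", read_id="r1",
            cigar=None, aln_strand=None):
    """Construct a BisRead with scalar or per-base qualities."""
    if np.isscalar(quals):
        quals = np.full(len(seq), int(quals), dtype=np.int32)
    else:
        quals = np.asarray(quals, dtype=np.int32)
    if aln_strand is None:
        aln_strand = "+" if bs == "OT" else "-"
    return BisRead(read_id=read_id, chrom=chrom, start=start,
                   aln_strand=aln_strand, bs_strand=bs, seq=seq,
                   quals=quals, cigar=cigar)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)
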