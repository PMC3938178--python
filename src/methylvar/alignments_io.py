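"""Input layer: reference FASTA, SAM/BAM records, 5' trimming and pileup.

Bisulfite reads are normalised into :class:`BisRead` records carrying an
original-strand label (OT = read derives from the genomic top strand,
OB = bottom strand).  All coordinates are 0-based half-open internally;
1-based coordinates appear only in output writers.

The pileup keeps per-position, per-bisulfite-strand base and quality-sum
counts restricted to calls passing the minimum PHRED score (``minQ``), the
shared substrate of methylation profiling and SNV calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
OT, OB = "OT", "OB"
STRAND_INDEX = {OT: 0, OB: 1}

# CIGAR operations: (consumes query, consumes reference)
_CIGAR_CONSUMES = {
    "M": (True, True),
    "I": (True, False),
    "D": (False, True),
    "N": (False, True),
    "S": (True, False),
    "H": (False, False),
    "P": (False, False),
    "=": (True, True),
    "X": (True, True),
}


class DuplicateSequenceError(ValueError):
    """Raised when a FASTA file contains two records with the same name."""


@dataclass
class Config:
    """Pipeline parameters, named after the tool's command-line flags.

    ``minQ`` gates every base call (profiling and SNV evidence alike);
    ``seedLen`` is the 5' high-quality seed used for clonal-read detection;
    ``bisFailureFrac`` is the minimum fraction of unconverted non-CpG
    cytosines that marks a read as a bisulfite-conversion failure.
    """

    minQ: int = 20
    seedLen: int = 26
    trim5: int = 0
    dedup_enabled: bool = False
    bisFailureFrac: float = 0.9
    bisFailureEnabled: bool = True
    minDepthMeth: int = 3
    minDepthSNV: int = 1
    varFraction: float = 0.1
    maxPval: float = 0.05
    errorInterval: float = 0.1
    snvErrRate: float = 0.01
    fdr_enabled: bool = False
    fdr_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bisFailureFrac", "varFraction", "maxPval",
                     "errorInterval", "snvErrRate", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.minDepthSNV < 1:
            raise ValueError("minDepthSNV must be >= 1")
        if self.seedLen < 1:
            raise ValueError("seedLen must be >= 1")
        if self.trim5 < 0:
            raise ValueError("trim5 must be >= 0")


@dataclass
class BisRead:
    """One aligned bisulfite read in '+'-strand (SAM) orientation."""

    read_id: str
    chrom: str
    start: int  # 0-based leftmost aligned reference position
    aln_strand: str  # '+' or '-'
    bs_strand: str  # OT or OB
    seq: str
    quals: np.ndarray  # PHRED integers, len == len(seq)
    mapq: int = 60
    cigar: Optional[List[Tuple[str, int]]] = None  # None => all-M

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("seq and quals length mismatch")
        if self.start < 0:
            raise ValueError("negative start coordinate")

    @property
    def cigartuples(self) -> List[Tuple[str, int]]:
        if self.cigar is None:
            return [("M", len(self.seq))]
        return self.cigar

    def aligned_pairs(self) -> Iterator[Tuple[int, int]]:
        """Yield (query_pos, ref_pos) for every aligned (M/=/X) base."""
        q, r = 0, self.start
        for op, length in self.cigartuples:
            cq, cr = _CIGAR_CONSUMES[op]
            if cq and cr:
                for k in range(length):
                    yield q + k, r + k
            if cq:
                q += length
            if cr:
                r += length

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + sum(
            n for op, n in self.cigartuples if _CIGAR_CONSUMES[op][1]
        )


@dataclass
class PileupColumn:
    """Per-position, per-bisulfite-strand base calls passing minQ."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    qual_sums: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def depth(self) -> int:
        return sum(self.counts.values())


def load_reference(path: str) -> Dict[str, str]:
    """Read a FASTA file into a {name: uppercase sequence} mapping.

    The sequence name is the first whitespace-delimited token of the header.
    Duplicate names and empty files are errors.
    """
    seqs: Dict[str, str] = {}
    name = None
    parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts).upper()
                name = line[1:].split()[0] if line[1:].split() else ""
                if name in seqs:
                    raise DuplicateSequenceError(
                        f"duplicate sequence name {name!r} in {path}")
                parts = []
            elif line:
                if name is None:
                    raise ValueError(f"{path}: sequence data before header")
                parts.append(line)
    if name is not None:
        if name in seqs:
            raise DuplicateSequenceError(
                f"duplicate sequence name {name!r} in {path}")
        seqs[name] = "".join(parts).upper()
    if not seqs:
        raise ValueError(f"{path}: empty FASTA file")
    return seqs


def assign_bisulfite_strand(rec: pysam.AlignedSegment) -> str:
    """Infer the bisulfite (original) strand of an aligned read.

    A Bismark-style ``XG:Z:CT``/``XG:Z:GA`` tag takes precedence; otherwise
    the FLAG reverse bit is used under the directional-protocol assumption
    (forward alignment = original top strand).
    """
    tag_strand = None
    if rec.has_tag("XG"):
        xg = rec.get_tag("XG")
        if xg == "CT":
            tag_strand = OT
        elif xg == "GA":
            tag_strand = OB
        else:
            raise ValueError(f"unparseable XG tag {xg!r}")
    flag_strand = OB if rec.is_reverse else OT
    if tag_strand is not None:
        if tag_strand != flag_strand:
            logger.warning(
                "read %s: XG tag (%s) contradicts FLAG (%s); tag wins",
                rec.query_name, tag_strand, flag_strand)
        return tag_strand
    return flag_strand


def read_sam(path: str, chrom: Optional[str] = None,
             counters: Optional[Dict[str, int]] = None) -> Iterator[BisRead]:
    """Stream BisRead records from a coordinate-sorted SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped, as are
    records whose bisulfite strand cannot be determined; skip counts are
    accumulated in ``counters`` when given.
    """
    if counters is None:
        counters = {}
    with pysam.AlignmentFile(path, check_sq=False) as af:
        it = af.fetch(chrom) if (chrom and af.has_index()) else af
        for rec in it:
            if chrom is not None and rec.reference_name != chrom:
                continue
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counters["skipped_flag"] = counters.get("skipped_flag", 0) + 1
                continue
            try:
                bs = assign_bisulfite_strand(rec)
            except ValueError:
                counters["skipped_bs"] = counters.get("skipped_bs", 0) + 1
                continue
            cigar = None
            if rec.cigartuples is not None and any(
                    op != 0 for op, _ in rec.cigartuples):
                cigar = [("MIDNSHP=XB"[op], n) for op, n in rec.cigartuples]
            yield BisRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                aln_strand="-" if rec.is_reverse else "+",
                bs_strand=bs,
                seq=rec.query_sequence.upper(),
                quals=np.asarray(rec.query_qualities, dtype=np.int32),
                mapq=rec.mapping_quality,
                cigar=cigar,
            )
            counters["reads_in"] = counters.get("reads_in", 0) + 1


def trim_5prime(read: BisRead, n: int) -> Optional[BisRead]:
    """Remove ``n`` bases from the sequencing 5' end of a read.

    For a forward-aligned read the 5' end is the leftmost aligned base, so
    the start coordinate advances; for a reverse-aligned read it is the
    rightmost base and the right end is clipped.  Returns ``None`` (read
    dropped) if ``n`` is at least the read length.
    """
    if n < 0:
        raise ValueError("trim length must be >= 0")
    if n == 0:
        return read
    if n >= len(read.seq):
        return None
    from_left = read.aln_strand == "+"
    ops = list(read.cigartuples)
    if not from_left:
        ops = ops[::-1]
    remaining = n
    ref_consumed = 0
    new_ops: List[Tuple[str, int]] = []
    for i, (op, length) in enumerate(ops):
        cq, cr = _CIGAR_CONSUMES[op]
        if remaining == 0:
            new_ops.extend(ops[i:])
            break
        if not cq:
            if cr:
                ref_consumed += length  # deletion at the trim boundary
            continue
        take = min(remaining, length)
        if cr:
            ref_consumed += take
        remaining -= take
        if take < length:
            new_ops.append((op, length - take))
            new_ops.extend(ops[i + 1:])
            break
    if not from_left:
        new_ops = new_ops[::-1]
    if from_left:
        seq = read.seq[n:]
        quals = read.quals[n:]
        start = read.start + ref_consumed
    else:
        seq = read.seq[:-n]
        quals = read.quals[:-n]
        start = read.start
    cigar = None if all(op == "M" for op, _ in new_ops) and len(new_ops) == 1 \
        else new_ops
    return replace(read, seq=seq, quals=quals, start=start, cigar=cigar)


class PileupMatrix:
    """Dense per-contig pileup: counts[pos, strand(OT/OB), base(ACGT)].

    Base calls below ``minQ`` and 'N' calls are excluded.  ``qual_sums``
    accumulates the PHRED scores of the counted calls.
    """

    def __init__(self, chrom: str, ref_seq: str, minQ: int):
        self.chrom = chrom
        self.ref_seq = ref_seq
        self.minQ = minQ
        L = len(ref_seq)
        self.counts = np.zeros((L, 2, 4), dtype=np.int32)
        self.qual_sums = np.zeros((L, 2, 4), dtype=np.int64)
        self.n_reads = 0
        self.skipped_out_of_range = 0

    def add_read(self, read: BisRead) -> None:
        L = len(self.ref_seq)
        if read.end > L or read.start >= L:
            self.skipped_out_of_range += 1
            logger.debug("read %s extends beyond contig end; skipped",
                         read.read_id)
            return
        s = STRAND_INDEX[read.bs_strand]
        if read.cigar is None:
            qpos = np.arange(len(read.seq))
            rpos = read.start + qpos
        else:
            pairs = list(read.aligned_pairs())
            if not pairs:
                return
            qpos = np.array([p[0] for p in pairs])
            rpos = np.array([p[1] for p in pairs])
        codes = np.frombuffer(read.seq.encode(), dtype=np.uint8)[qpos]
        base_idx = _BASE_CODE_LUT[codes]
        quals = read.quals[qpos]
        ok = (base_idx >= 0) & (quals >= self.minQ)
        np.add.at(self.counts[:, s, :], (rpos[ok], base_idx[ok]), 1)
        np.add.at(self.qual_sums[:, s, :], (rpos[ok], base_idx[ok]),
                  quals[ok])
        self.n_reads += 1

    def column(self, pos: int) -> PileupColumn:
        col = PileupColumn(self.chrom, pos, self.ref_seq[pos])
        for strand, s in STRAND_INDEX.items():
            for base, b in BASE_INDEX.items():
                c = int(self.counts[pos, s, b])
                if c:
                    col.counts[(strand, base)] = c
                    col.qual_sums[(strand, base)] = int(
                        self.qual_sums[pos, s, b])
        return col

    def covered_positions(self) -> np.ndarray:
        return np.nonzero(self.counts.sum(axis=(1, 2)))[0]

    def iter_columns(self) -> Iterator[PileupColumn]:
        for pos in self.covered_positions():
            yield self.column(int(pos))


_BASE_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODE_LUT[ord(_b)] = _i


def build_pileup(reads: Iterable[BisRead], ref: Dict[str, str],
                 minQ: int) -> Iterator[PileupColumn]:
    """Build pileup columns from coordinate-sorted reads, one contig at a
    time, and yield covered columns in coordinate order."""
    current: Optional[PileupMatrix] = None
    for read in reads:
        if current is None or read.chrom != current.chrom:
            if current is not None:
                yield from current.iter_columns()
            if read.chrom not in ref:
                raise KeyError(f"read contig {read.chrom!r} not in reference")
            current = PileupMatrix(read.chrom, ref[read.chrom], minQ)
        current.add_read(read)
    if current is not None:
        yield from current.iter_columns()
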