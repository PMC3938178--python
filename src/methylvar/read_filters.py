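"""Read-level quality filters: clonal-read selection and bisulfite-failure
elimination.

Clonal (PCR duplicate) reads are grouped by start coordinate *and* by the
high-quality 5' seed sequence, so that two reads carrying different alleles
at the same start are never collapsed.  The bisulfite-failure filter drops
reads in which nearly all non-CpG-context cytosines read as unconverted —
the signature of a molecule the bisulfite treatment failed to convert.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np

from .alignments_io import OB, OT, BisRead


def read_seed(read: BisRead, seedLen: int, minQ: int) -> str:
    """High-quality seed: among the first ``seedLen`` bases from the
    sequencing 5' end, keep those with quality >= minQ, in read order."""
    if seedLen < 1:
        raise ValueError("seedLen must be >= 1")
    if read.aln_strand == "+":
        seq = read.seq[:seedLen]
        quals = read.quals[:seedLen]
    else:
        # sequencing 5' end of a reverse-aligned read is its right end
        seq = read.seq[::-1][:seedLen]
        quals = read.quals[::-1][:seedLen]
    return "".join(b for b, q in zip(seq, quals) if q >= minQ)


def _hiq_count(read: BisRead, minQ: int) -> int:
    return int(np.count_nonzero(read.quals >= minQ))


def deduplicate(group: List[BisRead], seedLen: int, minQ: int,
                rng: np.random.Generator) -> List[BisRead]:
    """Collapse putative clonal reads sharing (chrom, start, bs_strand).

    Reads are sub-grouped by identical high-quality seed; within a seed
    sub-group one read survives: most bases with quality >= minQ, then the
    longest read, then a uniform random pick.  Reads with different seeds
    (e.g. different alleles at a seed position) are all kept.
    """
    if not group:
        return []
    key0 = (group[0].chrom, group[0].start, group[0].bs_strand)
    for r in group:
        if (r.chrom, r.start, r.bs_strand) != key0:
            raise ValueError("dedup group must share (chrom, start, bs_strand)")
    by_seed: Dict[str, List[BisRead]] = defaultdict(list)
    for r in group:
        by_seed[read_seed(r, seedLen, minQ)].append(r)
    kept: List[BisRead] = []
    for seed in sorted(by_seed):
        sub = by_seed[seed]
        best_key = max((_hiq_count(r, minQ), len(r.seq)) for r in sub)
        best = [r for r in sub
                if (_hiq_count(r, minQ), len(r.seq)) == best_key]
        if len(best) == 1:
            kept.append(best[0])
        else:
            best.sort(key=lambda r: (r.read_id, r.seq))
            kept.append(best[int(rng.integers(len(best)))])
    kept.sort(key=lambda r: r.read_id)
    return kept


def deduplicate_stream(reads: Iterable[BisRead], seedLen: int, minQ: int,
                       rng: np.random.Generator,
                       counters: Dict[str, int] | None = None
                       ) -> Iterator[BisRead]:
    """Apply :func:`deduplicate` over a coordinate-sorted read stream."""
    if counters is None:
        counters = {}
    pending: Dict[Tuple[str, int, str], List[BisRead]] = defaultdict(list)
    current: Tuple[str, int] | None = None
    for read in reads:
        key = (read.chrom, read.start)
        if current is not None and key != current:
            for gkey in sorted(pending):
                out = deduplicate(pending[gkey], seedLen, minQ, rng)
                counters["dup_dropped"] = (counters.get("dup_dropped", 0)
                                           + len(pending[gkey]) - len(out))
                yield from out
            pending.clear()
        current = key
        pending[(read.chrom, read.start, read.bs_strand)].append(read)
    for gkey in sorted(pending):
        out = deduplicate(pending[gkey], seedLen, minQ, rng)
        counters["dup_dropped"] = (counters.get("dup_dropped", 0)
                                   + len(pending[gkey]) - len(out))
        yield from out


def bisulfite_failure_filter(read: BisRead, ref: Dict[str, str],
                             frac_threshold: float, minQ: int = 20) -> bool:
    """Return True (keep) unless the read looks like a conversion failure.

    A non-CpG-context cytosine is a reference C on the read's bisulfite
    strand whose next base on that strand is not G (for OB reads: a
    reference G at position p with reference base at p-1 != C).  Only
    quality-passing calls are counted.  The read is dropped when the
    unconverted fraction u/n reaches ``frac_threshold`` (n > 0).
    """
    ref_seq = ref[read.chrom]
    L = len(ref_seq)
    n = 0
    u = 0
    if read.bs_strand == OT:
        cyt, unconv = "C", "C"
    else:
        cyt, unconv = "G", "G"
    for qpos, rpos in read.aligned_pairs():
        if rpos >= L or read.quals[qpos] < minQ:
            continue
        if ref_seq[rpos] != cyt:
            continue
        if read.bs_strand == OT:
            if rpos + 1 < L and ref_seq[rpos + 1] == "G":
                continue  # CpG context
        else:
            if rpos - 1 >= 0 and ref_seq[rpos - 1] == "C":
                continue
        n += 1
        if read.seq[qpos] == unconv:
            u += 1
    if n == 0:
        return True
    return (u / n) < frac_threshold


def failure_filter_stream(reads: Iterable[BisRead], ref: Dict[str, str],
                          frac_threshold: float, minQ: int,
                          counters: Dict[str, int] | None = None
                          ) -> Iterator[BisRead]:
    if counters is None:
        counters = {}
    for read in reads:
        if bisulfite_failure_filter(read, ref, frac_threshold, minQ):
            yield read
        else:
            counters["bisfail_dropped"] = counters.get("bisfail_dropped", 0) + 1
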