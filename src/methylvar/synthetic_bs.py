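"""Synthetic bisulfite-sequencing data with known ground truth.

The generator emulates the full error structure the pipeline is built to
control: a diploid genome with planted homozygous/heterozygous SNVs,
per-cytosine methylation states (fully methylated or fully unmethylated
CpGs, unmethylated non-CpG cytosines), incomplete bisulfite conversion at
a stated rate, and quality-dependent sequencing errors.  Reads are drawn
from both haplotypes and both original strands and emitted as
truth-perfect alignments (SAM) plus FASTQ, so every pipeline stage can be
benchmarked without an aligner.

Evaluation mirrors the standard benchmark on such data: SNV sensitivity
and positive predictive value against the planted variants, and the
fraction of profiled cytosines whose methylation level equals the
simulated truth exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignments_io import OB, OT, BisRead
from .methylation import CytosineSite, assign_context
from .snv_caller import SNVCall

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: parametric quality models: name -> (PHRED values, probabilities)
QUAL_MODELS = {
    "q30": (np.array([30]), np.array([1.0])),
    # heavy-tailed mix emulating the miscalibrated tail of real run quality
    "mixed": (np.array([8, 12, 25, 38]),
              np.array([0.08, 0.07, 0.15, 0.70])),
}

CPG_PRESETS = ("methylated", "unmethylated")


@dataclass
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alleles: Tuple[str, str]  # (hap1 base, hap2 base)

    @property
    def zygosity(self) -> str:
        return "hom" if self.alleles[0] == self.alleles[1] else "het"

    @property
    def genotype_set(self) -> frozenset:
        return frozenset(self.alleles)


@dataclass
class SimTruth:
    variants: List[Variant] = field(default_factory=list)
    #: truth methylation where BOTH haplotypes retain the cytosine:
    #: (chrom, pos, strand) -> (reference context, level in {0, 0.5, 1})
    meth_states: Dict[Tuple[str, int, str], Tuple[str, float]] = \
        field(default_factory=dict)
    conv_rate: float = 1.0
    #: per-read provenance: read_id -> (haplotype index, bs_strand, n errors)
    read_info: Dict[str, Tuple[int, str, int]] = field(default_factory=dict)

    def variant_index(self) -> Dict[Tuple[str, int], frozenset]:
        return {(v.chrom, v.pos): v.genotype_set for v in self.variants}


@dataclass
class EvalReport:
    sn: Optional[float]
    ppv: Optional[float]
    correct_meth_fraction: Optional[float]
    cpg_coverage_fraction: Optional[float]
    tp: int = 0
    fp: int = 0
    fn: int = 0
    n_meth_evaluated: int = 0


def random_genome(length: int, gc: float = 0.42,
                  rng: Optional[np.random.Generator] = None) -> str:
    """Random genome sequence with the given GC content (default 0.42,
    a typical mammalian value)."""
    rng = rng if rng is not None else np.random.default_rng()
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def simulate_diploid(ref: Dict[str, str], snv_density: float = 1e-3,
                     het_fraction: float = 0.5,
                     rng: Optional[np.random.Generator] = None
                     ) -> Tuple[List[Dict[str, str]], SimTruth]:
    """Plant SNVs on a diploid copy of ``ref``.

    Variant positions are uniform with the given per-bp density; each is
    heterozygous with probability ``het_fraction`` (alt on one random
    haplotype) and homozygous-alt otherwise.  Returns the two haplotypes
    and the truth record.
    """
    rng = rng if rng is not None else np.random.default_rng()
    truth = SimTruth()
    haps: List[Dict[str, str]] = [{}, {}]
    for chrom, seq in ref.items():
        L = len(seq)
        n_var = int(rng.binomial(L, snv_density)) if snv_density > 0 else 0
        h1 = bytearray(seq.encode())
        h2 = bytearray(seq.encode())
        if n_var:
            positions = rng.choice(L, size=n_var, replace=False)
            positions.sort()
            for pos in positions:
                pos = int(pos)
                ref_base = seq[pos]
                if ref_base not in "ACGT":
                    continue
                alt = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
                if rng.random() < het_fraction:
                    if rng.random() < 0.5:
                        alleles = (alt, ref_base)
                    else:
                        alleles = (ref_base, alt)
                else:
                    alleles = (alt, alt)
                h1[pos] = ord(alleles[0])
                h2[pos] = ord(alleles[1])
                truth.variants.append(Variant(chrom, pos, ref_base, alleles))
        haps[0][chrom] = h1.decode()
        haps[1][chrom] = h2.decode()
    return haps, truth


def _methylation_mask(hap_seq: str, cpg_preset: str) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean methylation state per position for the '+' and '-' strand
    cytosines of one haplotype (CpG cytosines take the preset state,
    non-CpG cytosines are unmethylated)."""
    arr = np.frombuffer(hap_seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    meth_plus = np.zeros(len(arr), dtype=bool)
    meth_minus = np.zeros(len(arr), dtype=bool)
    if cpg_preset == "methylated":
        meth_plus[:-1] = is_c[:-1] & is_g[1:]
        meth_minus[1:] = is_g[1:] & is_c[:-1]
    elif cpg_preset != "unmethylated":
        raise ValueError(f"unknown CpG preset {cpg_preset!r}")
    return meth_plus, meth_minus


def _record_meth_truth(ref: Dict[str, str], haps: Sequence[Dict[str, str]],
                       cpg_preset: str, truth: SimTruth) -> None:
    for chrom, seq in ref.items():
        masks = [_methylation_mask(h[chrom], cpg_preset) for h in haps]
        h_arr = [np.frombuffer(h[chrom].encode(), dtype=np.uint8)
                 for h in haps]
        r_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, code, mi in (("+", ord("C"), 0), ("-", ord("G"), 1)):
            both_c = (h_arr[0] == code) & (h_arr[1] == code) & (r_arr == code)
            for pos in np.nonzero(both_c)[0]:
                pos = int(pos)
                ctx = assign_context(seq, pos, strand)
                if ctx is None:
                    continue
                level = (int(masks[0][mi][pos]) + int(masks[1][mi][pos])) / 2.0
                truth.meth_states[(chrom, pos, strand)] = (ctx, float(level))


def simulate_reads(haps: Sequence[Dict[str, str]], truth: SimTruth,
                   coverage: float = 20.0, read_len: int = 100,
                   conv_rate: float = 0.99, qual_model: str = "q30",
                   sequencing_errors: bool = True,
                   cpg_preset: str = "methylated",
                   ref: Optional[Dict[str, str]] = None,
                   rng: Optional[np.random.Generator] = None
                   ) -> List[BisRead]:
    """Draw bisulfite reads uniformly from both haplotypes and strands.

    Each unmethylated cytosine on the read's original strand converts with
    probability ``conv_rate``; methylated cytosines never convert.
    Per-base sequencing errors occur with probability 10^(-Q/10) under the
    chosen quality model.  Reads are returned coordinate-sorted, in SAM
    ('+') orientation, with OT/OB labels; ``truth`` is updated with the
    methylation truth and per-read provenance.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = rng if rng is not None else np.random.default_rng()
    if ref is None:
        ref = haps[0]
    truth.conv_rate = conv_rate
    if not truth.meth_states:
        _record_meth_truth(ref, haps, cpg_preset, truth)
    qual_values, qual_probs = QUAL_MODELS[qual_model]
    reads: List[BisRead] = []
    for chrom in ref:
        L = len(ref[chrom])
        if read_len > L:
            raise ValueError(f"read_len {read_len} exceeds contig "
                             f"{chrom} length {L}")
        hap_arr = [np.frombuffer(h[chrom].encode(), dtype=np.uint8)
                   for h in haps]
        meth = [_methylation_mask(h[chrom], cpg_preset) for h in haps]
        n_reads = int(round(coverage * L / read_len))
        starts = rng.integers(0, L - read_len + 1, size=n_reads)
        starts.sort()
        hap_pick = rng.integers(0, 2, size=n_reads)
        strand_pick = rng.integers(0, 2, size=n_reads)
        for i in range(n_reads):
            start = int(starts[i])
            hap = int(hap_pick[i])
            bs = OT if strand_pick[i] == 0 else OB
            seq = hap_arr[hap][start:start + read_len].copy()
            # bisulfite conversion of unmethylated cytosines on the
            # original strand, in '+' display orientation
            if bs == OT:
                cyt = seq == ord("C")
                meth_mask = meth[hap][0][start:start + read_len]
                to_base = ord("T")
            else:
                cyt = seq == ord("G")
                meth_mask = meth[hap][1][start:start + read_len]
                to_base = ord("A")
            convertible = cyt & ~meth_mask
            n_conv = int(convertible.sum())
            if n_conv:
                converts = rng.random(n_conv) < conv_rate
                idx = np.nonzero(convertible)[0][converts]
                seq[idx] = to_base
            if len(qual_values) == 1:
                quals = np.full(read_len, int(qual_values[0]), dtype=np.int32)
            else:
                quals = rng.choice(qual_values, size=read_len,
                                   p=qual_probs).astype(np.int32)
            n_err = 0
            if sequencing_errors:
                err_mask = rng.random(read_len) < 10.0 ** (-quals / 10.0)
                err_idx = np.nonzero(err_mask)[0]
                n_err = len(err_idx)
                if n_err:
                    shifts = rng.integers(1, 4, size=n_err)
                    for j, s in zip(err_idx, shifts):
                        cur = "ACGT".index(chr(seq[j]))
                        seq[j] = ord("ACGT"[(cur + int(s)) % 4])
            read_id = f"sim:{chrom}:{i}"
            reads.append(BisRead(
                read_id=read_id, chrom=chrom, start=start,
                aln_strand="+" if bs == OT else "-", bs_strand=bs,
                seq=seq.tobytes().decode(), quals=quals))
            truth.read_info[read_id] = (hap, bs, n_err)
    return reads


def write_sam(reads: Iterable[BisRead], ref: Dict[str, str],
              path: str) -> None:
    """Write reads as a coordinate-sorted SAM file with XG bisulfite tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.items()],
    }
    chrom_ids = {c: i for i, c in enumerate(ref)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.query_sequence = read.seq
            a.flag = 16 if read.aln_strand == "-" else 0
            a.reference_id = chrom_ids[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = read.mapq
            a.cigartuples = [("MIDNSHP=X".index(op), n)
                             for op, n in read.cigartuples]
            a.query_qualities = [int(q) for q in read.quals]
            a.set_tag("XG", "CT" if read.bs_strand == OT else "GA")
            out.write(a)


def write_fastq(reads: Iterable[BisRead], path: str) -> None:
    """Write reads as FASTQ in sequencing orientation (OB reads are
    reverse-complemented back to the strand that was read)."""
    with open(path, "w") as fh:
        for read in reads:
            if read.aln_strand == "-":
                seq = read.seq.translate(_COMPLEMENT)[::-1]
                quals = read.quals[::-1]
            else:
                seq, quals = read.seq, read.quals
            qstr = "".join(chr(int(q) + 33) for q in quals)
            fh.write(f"@{read.read_id}\n{seq}\n+\n{qstr}\n")


def write_truth_tables(truth: SimTruth, variants_path: str,
                       meth_path: str) -> None:
    with open(variants_path, "w") as fh:
        fh.write("#chrom\tpos\tref\thap1\thap2\tzygosity\n")
        for v in truth.variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alleles[0]}\t"
                     f"{v.alleles[1]}\t{v.zygosity}\n")
    with open(meth_path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tlevel\n")
        for (chrom, pos, strand), (ctx, level) in sorted(
                truth.meth_states.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            fh.write(f"{chrom}\t{pos + 1}\t{strand}\t{ctx}\t{level}\n")


def benchmark_pipeline(seed: int, length: int = 1_000_000,
                       snv_density: float = 1e-3, het_fraction: float = 0.5,
                       coverage: float = 20.0, read_len: int = 100,
                       conv_rate: float = 0.99, qual_model: str = "q30",
                       cpg_preset: str = "methylated",
                       cfg=None):
    """Simulate a diploid genome, run the full pipeline and score it.

    Returns ``(report, sites, calls, truth, ref, reads)`` so callers can
    re-analyse the same simulated reads under different parameter settings.
    """
    from .alignments_io import Config
    from .pipeline import analyze_reads

    rng = np.random.default_rng(seed)
    ref = {"sim1": random_genome(length, rng=rng)}
    haps, truth = simulate_diploid(ref, snv_density, het_fraction, rng)
    reads = simulate_reads(haps, truth, coverage=coverage, read_len=read_len,
                           conv_rate=conv_rate, qual_model=qual_model,
                           cpg_preset=cpg_preset, ref=ref, rng=rng)
    cfg = cfg if cfg is not None else Config()
    sites, calls, _ = analyze_reads(iter(reads), ref, cfg)
    return evaluate(calls, sites, truth), sites, calls, truth, ref, reads


def evaluate(calls: Sequence[SNVCall], sites: Sequence[CytosineSite],
             truth: SimTruth) -> EvalReport:
    """Score SNV calls and methylation profiles against the planted truth.

    A call is a true positive only if its genotype matches the planted
    genotype at that position; calls at non-variant positions or with a
    wrong genotype are false positives.  Methylation accuracy is the
    fraction of profiled cytosines (with defined truth, i.e. both
    haplotypes retain the cytosine) whose level equals the simulated level
    exactly.
    """
    var_idx = truth.variant_index()
    tp = fp = 0
    found = set()
    for call in calls:
        key = (call.chrom, call.pos)
        if key in var_idx and call.genotype_set == var_idx[key]:
            tp += 1
            found.add(key)
        else:
            fp += 1
    fn = len(var_idx) - len(found)
    sn = tp / len(var_idx) if var_idx else None
    ppv = tp / (tp + fp) if (tp + fp) else None

    n_eval = n_correct = 0
    cpg_profiled = 0
    for s in sites:
        entry = truth.meth_states.get((s.chrom, s.pos, s.strand))
        if entry is None:
            continue
        _, level = entry
        n_eval += 1
        if s.level == level:
            n_correct += 1
        if s.context == "CG":
            cpg_profiled += 1
    n_cpg_truth = sum(1 for (ctx, _) in truth.meth_states.values()
                      if ctx == "CG")
    return EvalReport(
        sn=sn, ppv=ppv,
        correct_meth_fraction=n_correct / n_eval if n_eval else None,
        cpg_coverage_fraction=cpg_profiled / n_cpg_truth if n_cpg_truth else None,
        tp=tp, fp=fp, fn=fn, n_meth_evaluated=n_eval)
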