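"""End-to-end analysis: reads -> filters -> pileup -> methylation + SNVs.

The two outputs share one pass over the pileup.  SNV genotypes feed back
into the methylation table: a cytosine whose genotype removes the C on
both chromosomes is suppressed (no cytosine exists in the sample), and a
heterozygous genotype is flagged on the profiled record.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .alignments_io import (BisRead, Config, PileupMatrix, load_reference,
                            read_sam, trim_5prime)
from .methylation import CytosineSite, profile_matrix
from .read_filters import deduplicate_stream, failure_filter_stream
from .snv_caller import SNVCall, call_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    reads_in: int = 0
    reads_kept: int = 0
    trim_dropped: int = 0
    dup_dropped: int = 0
    bisfail_dropped: int = 0
    skipped_unusable: int = 0
    sites_per_context: Dict[str, int] = field(default_factory=dict)
    snv_calls: int = 0
    snv_hom: int = 0
    snv_het: int = 0
    meth_suppressed: int = 0
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def apply_read_filters(reads: Iterable[BisRead], ref: Dict[str, str],
                       cfg: Config, report: RunReport,
                       rng: Optional[np.random.Generator] = None
                       ) -> Iterable[BisRead]:
    """Compose 5' trimming, optional deduplication and the
    bisulfite-failure filter over a sorted read stream."""
    def trimmed() -> Iterable[BisRead]:
        for read in reads:
            report.reads_in += 1
            if cfg.trim5:
                read = trim_5prime(read, cfg.trim5)
                if read is None:
                    report.trim_dropped += 1
                    continue
            yield read

    stream: Iterable[BisRead] = trimmed()
    counters: Dict[str, int] = {}
    if cfg.dedup_enabled:
        rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
        stream = deduplicate_stream(stream, cfg.seedLen, cfg.minQ, rng,
                                    counters)
    if cfg.bisFailureEnabled:
        stream = failure_filter_stream(stream, ref, cfg.bisFailureFrac,
                                       cfg.minQ, counters)
    for read in stream:
        report.reads_kept += 1
        yield read
    report.dup_dropped = counters.get("dup_dropped", 0)
    report.bisfail_dropped = counters.get("bisfail_dropped", 0)


def _strand_cytosine(strand: str) -> str:
    return "C" if strand == "+" else "G"


def annotate_sites_with_genotypes(sites: List[CytosineSite],
                                  calls: List[SNVCall],
                                  report: Optional[RunReport] = None
                                  ) -> List[CytosineSite]:
    """Apply the SNV feedback to the methylation table.

    Homozygous loss of the cytosine suppresses the record; any other
    overlapping het call flags the record with its genotype.
    """
    by_pos = {(c.chrom, c.pos): c for c in calls}
    out: List[CytosineSite] = []
    for site in sites:
        call = by_pos.get((site.chrom, site.pos))
        if call is None:
            out.append(site)
            continue
        cyt = _strand_cytosine(site.strand)
        if call.zygosity == "hom" and call.alleles[0] != cyt:
            if report is not None:
                report.meth_suppressed += 1
            continue
        if call.zygosity == "het":
            site.genotype = "/".join(call.alleles)
        out.append(site)
    return out


def analyze_reads(reads: Iterable[BisRead], ref: Dict[str, str], cfg: Config,
                  report: Optional[RunReport] = None
                  ) -> Tuple[List[CytosineSite], List[SNVCall], RunReport]:
    """Run filters, pileup, methylation profiling and SNV calling on an
    in-memory (coordinate-sorted) read stream."""
    if report is None:
        report = RunReport()
    report.started = time.time()
    rng = np.random.default_rng(cfg.rng_seed)
    filtered = apply_read_filters(reads, ref, cfg, report, rng)

    sites: List[CytosineSite] = []
    calls: List[SNVCall] = []
    current: Optional[PileupMatrix] = None

    def flush(mat: Optional[PileupMatrix]) -> None:
        if mat is None:
            return
        chrom_calls = call_matrix(mat, cfg)
        chrom_sites = annotate_sites_with_genotypes(
            list(profile_matrix(mat, cfg)), chrom_calls, report)
        sites.extend(chrom_sites)
        calls.extend(chrom_calls)

    for read in filtered:
        if current is None or read.chrom != current.chrom:
            flush(current)
            if read.chrom not in ref:
                raise KeyError(f"read contig {read.chrom!r} not in reference")
            current = PileupMatrix(read.chrom, ref[read.chrom], cfg.minQ)
        current.add_read(read)
    flush(current)

    for s in sites:
        report.sites_per_context[s.context] = \
            report.sites_per_context.get(s.context, 0) + 1
    report.snv_calls = len(calls)
    report.snv_hom = sum(1 for c in calls if c.zygosity == "hom")
    report.snv_het = len(calls) - report.snv_hom
    report.finished = time.time()
    return sites, calls, report


def run_pipeline(ref_path: str, aln_path: str, cfg: Config
                 ) -> Tuple[List[CytosineSite], List[SNVCall], RunReport]:
    """File-level entry point: FASTA + sorted SAM/BAM -> sites + calls."""
    ref = load_reference(ref_path)
    report = RunReport()
    counters: Dict[str, int] = {}
    reads = read_sam(aln_path, counters=counters)
    sites, calls, report = analyze_reads(reads, ref, cfg, report)
    report.skipped_unusable = (counters.get("skipped_flag", 0)
                               + counters.get("skipped_bs", 0))
    return sites, calls, report
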