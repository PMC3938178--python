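"""SNV detection from bisulfite-converted reads.

Bisulfite conversion destroys part of the base-calling evidence: on reads
from the original top strand (OT) a T call may be a converted C, and on
original-bottom (OB) reads an A call may be a converted G.  Those calls are
therefore discarded before allele counting; the remaining usable counts
feed a VarScan-style caller: candidate alleles by relative frequency
(``varFraction``), a one-sided Fisher exact test of the observed
ref/variant split against the split expected from sequencing error alone,
and genotype assignment from the two highest-frequency alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Set, TextIO, Tuple

import numpy as np
from scipy.stats import fisher_exact

from .alignments_io import BASE_INDEX, BASES, Config, PileupColumn, PileupMatrix

# calls confounded by conversion: (bisulfite strand, base) pairs discarded
CONFOUNDED = {("OT", "T"), ("OB", "A")}


@dataclass
class SNVCall:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alleles: Tuple[str, str]  # genotype, ref first when present
    allele_counts: Dict[str, int]
    depth_usable: int
    p_value: float

    @property
    def zygosity(self) -> str:
        return "hom" if self.alleles[0] == self.alleles[1] else "het"

    @property
    def genotype_set(self) -> frozenset:
        return frozenset(self.alleles)


def usable_allele_counts(column: PileupColumn) -> Dict[str, int]:
    """Allele counts usable as variant evidence, summed across strands.

    From OT reads T calls are discarded (confounded with converted C);
    from OB reads A calls are discarded (confounded with converted G).
    """
    out: Dict[str, int] = {}
    for (strand, base), c in column.counts.items():
        if (strand, base) in CONFOUNDED:
            continue
        out[base] = out.get(base, 0) + c
    return out


def detect_candidates(counts: Dict[str, int], ref_base: str,
                      varFraction: float, minDepthSNV: int) -> Set[str]:
    """Non-reference bases whose relative frequency reaches ``varFraction``;
    empty below the minimum usable depth."""
    total = sum(counts.values())
    if total < minDepthSNV or total == 0:
        return set()
    return {b for b, c in counts.items()
            if b != ref_base and c / total >= varFraction}


def variant_pvalue(counts: Dict[str, int], ref_base: str,
                   candidates: Set[str], err_rate: float = 0.01) -> float:
    """One-sided Fisher exact test of variant enrichment.

    The observed row (ref count vs summed candidate counts) is tested
    against the row expected if all non-reference calls were sequencing
    errors at rate ``err_rate``: [round(N(1-e)), round(N*e)].
    """
    n_var = sum(counts.get(b, 0) for b in candidates)
    n_ref = counts.get(ref_base, 0)
    n_tot = sum(counts.values())
    if n_tot == 0:
        return 1.0
    if n_var == 0:
        return 1.0
    exp_var = round(n_tot * err_rate)
    exp_ref = n_tot - exp_var
    # alternative='less': tables with fewer ref (more variant) calls in the
    # observed row are the enrichment direction
    _, p = fisher_exact([[n_ref, n_var], [exp_ref, exp_var]],
                        alternative="less")
    return float(min(max(p, 0.0), 1.0))


def call_genotype(counts: Dict[str, int], ref_base: str,
                  candidates: Set[str], p_value: float,
                  cfg: Config, chrom: str = "", pos: int = 0
                  ) -> Optional[SNVCall]:
    """Assign the genotype of a significant variant position.

    The two highest-count bases among {ref} + candidates form the genotype;
    when the runner-up's frequency is below ``varFraction`` the call is
    homozygous for the top base.  Ties break on the fixed order A<C<G<T.
    """
    if not candidates or p_value >= cfg.maxPval:
        return None
    total = sum(counts.values())
    pool = sorted({ref_base} | candidates)
    ranked = sorted(pool, key=lambda b: (-counts.get(b, 0), b))
    top = ranked[0]
    second = ranked[1] if len(ranked) > 1 else top
    if counts.get(second, 0) / total < cfg.varFraction:
        alleles = (top, top)
    else:
        alleles = (second, top) if second == ref_base else (top, second)
        if ref_base in alleles and alleles[0] != ref_base:
            alleles = (alleles[1], alleles[0])
    return SNVCall(chrom, pos, ref_base, alleles,
                   {b: counts.get(b, 0) for b in sorted(set(counts) | set(alleles))},
                   total, p_value)


def call_column(column: PileupColumn, cfg: Config) -> Optional[SNVCall]:
    """Full per-column calling path (counting -> candidates -> test -> call)."""
    if column.ref_base not in BASES:
        return None
    counts = usable_allele_counts(column)
    cands = detect_candidates(counts, column.ref_base,
                              cfg.varFraction, cfg.minDepthSNV)
    if not cands:
        return None
    p = variant_pvalue(counts, column.ref_base, cands, cfg.snvErrRate)
    return call_genotype(counts, column.ref_base, cands, p, cfg,
                         column.chrom, column.pos)


def call_matrix(pileup: PileupMatrix, cfg: Config) -> List[SNVCall]:
    """Call SNVs over a dense per-contig pileup.

    Candidate screening is vectorised; the Fisher test runs only on the
    (rare) positions that pass the frequency and depth screens.
    """
    iA, iT = BASE_INDEX["A"], BASE_INDEX["T"]
    usable = pileup.counts.sum(axis=1).astype(np.int64)  # (L, 4)
    usable[:, iT] -= pileup.counts[:, 0, iT]  # OT T confounded
    usable[:, iA] -= pileup.counts[:, 1, iA]  # OB A confounded
    total = usable.sum(axis=1)
    ref = np.frombuffer(pileup.ref_seq.encode(), dtype=np.uint8)
    ref_idx = np.full(len(ref), -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        ref_idx[ref == ord(b)] = i
    ok = (total >= cfg.minDepthSNV) & (ref_idx >= 0)
    thr = np.where(ok, cfg.varFraction * total, np.inf)
    nonref = usable.copy().astype(np.float64)
    rows = np.nonzero(ok)[0]
    nonref[rows, ref_idx[rows]] = -1.0
    has_candidate = ok & ((nonref >= thr[:, None]) & (nonref > 0)).any(axis=1)
    calls: List[SNVCall] = []
    for pos in np.nonzero(has_candidate)[0]:
        call = call_column(pileup.column(int(pos)), cfg)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# VCF output

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Usable read depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
    '"Allelic depths (usable calls)">',
]


def write_vcf(calls: Sequence[SNVCall], ref: Dict[str, str],
              fh: TextIO, sample_name: str = "sample") -> None:
    """Write calls as VCF v4.2; QUAL = -10*log10(p) capped at 255."""
    for line in VCF_HEADER_LINES:
        fh.write(line + "\n")
    for chrom, seq in ref.items():
        fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             f"{sample_name}\n")
    last: Tuple[str, int] | None = None
    chrom_order = {c: i for i, c in enumerate(ref)}
    for call in calls:
        key = (call.chrom, call.pos)
        if last is not None and (chrom_order[key[0]], key[1]) < \
                (chrom_order[last[0]], last[1]):
            raise ValueError("SNV calls must be in coordinate order")
        last = key
        ref_base = ref[call.chrom][call.pos]
        alts = sorted(set(a for a in call.alleles if a != ref_base))
        if not alts:
            continue
        if call.p_value <= 0:
            qual = 255.0
        else:
            qual = min(255.0, -10.0 * math.log10(call.p_value))
        allele_index = {ref_base: 0}
        for i, a in enumerate(alts, start=1):
            allele_index[a] = i
        gt = "/".join(str(allele_index[a])
                      for a in sorted(call.alleles, key=lambda a: allele_index[a]))
        ad = ",".join(str(call.allele_counts.get(a, 0))
                      for a in [ref_base] + alts)
        fh.write(f"{call.chrom}\t{call.pos + 1}\t.\t{ref_base}\t"
                 f"{','.join(alts)}\t{qual:.2f}\tPASS\t"
                 f"DP={call.depth_usable}\tGT:AD\t{gt}:{ad}\n")


def parse_vcf(fh: TextIO) -> Iterator[Tuple[str, int, str, List[str], str]]:
    """Minimal VCF reader for round-trip checks: yields
    (chrom, 0-based pos, ref, alts, GT)."""
    for line in fh:
        if line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        yield f[0], int(f[1]) - 1, f[3], f[4].split(","), f[9].split(":")[0]
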