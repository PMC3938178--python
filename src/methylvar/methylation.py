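"""Per-cytosine methylation profiling.

Every reference cytosine (on both strands) is assigned a sequence context
(CG, CHG or CHH with H = A/C/T) and profiled from the strand-matched pileup:
only reads from the bisulfite strand carrying the cytosine are informative
(OT for '+' cytosines, OB for '-').  The methylation level is the fraction
of unconverted calls among unconverted + converted calls; base calls that
match neither (evidence of sequence variation) are excluded from the ratio
and handled by the SNV caller.

Output writers cover the native tab format, BED6 and variableStep WIG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, TextIO, Tuple

import numpy as np

from .alignments_io import BASE_INDEX, Config, PileupColumn, PileupMatrix

CONTEXTS = ("CG", "CHG", "CHH")

TAB_HEADER = "#chrom\tpos\tstrand\tcontext\tmc\tcov\tmean_qual\tlevel"


@dataclass
class CytosineSite:
    """A profiled cytosine; ``pos`` is 0-based in '+'-strand coordinates."""

    chrom: str
    pos: int
    strand: str  # '+' or '-'
    context: str  # CG / CHG / CHH
    mc_count: int
    cov: int
    mean_qual: float
    genotype: Optional[str] = None  # flagged heterozygous genotype, e.g. "C/T"

    @property
    def level(self) -> float:
        return self.mc_count / self.cov


def assign_context(ref_seq: str, pos: int, strand: str) -> Optional[str]:
    """Sequence context of the cytosine at (pos, strand), read 5'->3' on its
    own strand; ``None`` when the two downstream bases run off the contig."""
    if strand == "+":
        if ref_seq[pos] != "C":
            raise ValueError(f"no C at +{pos}")
        if pos + 1 >= len(ref_seq):
            return None
        if ref_seq[pos + 1] == "G":
            return "CG"
        if pos + 2 >= len(ref_seq):
            return None
        return "CHG" if ref_seq[pos + 2] == "G" else "CHH"
    if ref_seq[pos] != "G":
        raise ValueError(f"no C at -{pos} ('+' base must be G)")
    # downstream on '-' strand moves leftwards in '+' coordinates
    if pos - 1 < 0:
        return None
    if ref_seq[pos - 1] == "C":
        return "CG"
    if pos - 2 < 0:
        return None
    return "CHG" if ref_seq[pos - 2] == "C" else "CHH"


def profile_site(column: PileupColumn, context: str,
                 cfg: Config, strand: str = "+") -> Optional[CytosineSite]:
    """Profile one cytosine from its pileup column.

    mc = unconverted calls, cov = unconverted + converted; other calls are
    not counted toward the ratio.  Returns None below ``minDepthMeth``.
    """
    if strand == "+":
        bs, unconv, conv = "OT", "C", "T"
    else:
        bs, unconv, conv = "OB", "G", "A"
    mc = column.counts.get((bs, unconv), 0)
    converted = column.counts.get((bs, conv), 0)
    cov = mc + converted
    if cov < cfg.minDepthMeth:
        return None
    qsum = (column.qual_sums.get((bs, unconv), 0)
            + column.qual_sums.get((bs, conv), 0))
    return CytosineSite(column.chrom, column.pos, strand, context,
                        mc, cov, round(qsum / cov, 2))


def profile_matrix(pileup: PileupMatrix, cfg: Config) -> Iterator[CytosineSite]:
    """Profile every reference cytosine of a contig, in coordinate order
    ('+' before '-' at equal position).  Vectorised over the dense pileup."""
    ref = np.frombuffer(pileup.ref_seq.encode(), dtype=np.uint8)
    iC, iG, iT, iA = (BASE_INDEX[b] for b in "CGTA")
    plus = np.nonzero(ref == ord("C"))[0]
    minus = np.nonzero(ref == ord("G"))[0]
    # informative counts per strand
    mc_p = pileup.counts[plus, 0, iC]
    cv_p = mc_p + pileup.counts[plus, 0, iT]
    mc_m = pileup.counts[minus, 1, iG]
    cv_m = mc_m + pileup.counts[minus, 1, iA]
    qs_p = pileup.qual_sums[plus, 0, iC] + pileup.qual_sums[plus, 0, iT]
    qs_m = pileup.qual_sums[minus, 1, iG] + pileup.qual_sums[minus, 1, iA]
    sites: List[Tuple[int, int, CytosineSite]] = []
    for strand, positions, mcs, covs, qs in (
            ("+", plus, mc_p, cv_p, qs_p),
            ("-", minus, mc_m, cv_m, qs_m)):
        order = 0 if strand == "+" else 1
        keep = covs >= cfg.minDepthMeth
        for pos, mc, cov, q in zip(positions[keep], mcs[keep],
                                   covs[keep], qs[keep]):
            ctx = assign_context(pileup.ref_seq, int(pos), strand)
            if ctx is None:
                continue
            sites.append((int(pos), order, CytosineSite(
                pileup.chrom, int(pos), strand, ctx,
                int(mc), int(cov), round(float(q) / int(cov), 2))))
    sites.sort(key=lambda t: (t[0], t[1]))
    for _, _, s in sites:
        yield s


# ---------------------------------------------------------------------------
# writers

def write_tab(sites: Iterable[CytosineSite], fh: TextIO) -> None:
    """Native tab format, 1-based positions, header line starting with '#'.

    Heterozygous sites flagged by the SNV caller carry a ninth genotype
    column; unflagged sites have eight columns.
    """
    fh.write(TAB_HEADER + "\n")
    for s in sites:
        line = (f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.context}\t"
                f"{s.mc_count}\t{s.cov}\t{s.mean_qual:.2f}\t{s.level:.2f}")
        if s.genotype is not None:
            line += f"\t{s.genotype}"
        fh.write(line + "\n")


def parse_tab(fh: TextIO) -> Iterator[CytosineSite]:
    """Parse the native tab format back into CytosineSite records."""
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        yield CytosineSite(f[0], int(f[1]) - 1, f[2], f[3],
                           int(f[4]), int(f[5]), float(f[6]),
                           genotype=f[8] if len(f) > 8 else None)


def write_bed(sites: Iterable[CytosineSite], fh: TextIO) -> None:
    """BED6: single-base 0-based half-open intervals, name = context,
    score = round(level * 1000)."""
    fh.write('track name="cytosine_methylation" type=bed\n')
    for s in sites:
        fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.context}\t"
                 f"{round(s.level * 1000)}\t{s.strand}\n")


def write_wig(sites: Iterable[CytosineSite], fh: TextIO) -> None:
    """variableStep WIG with 1-based positions and methylation level.

    The two strands share the track; sites arrive in coordinate order so a
    '+'/'-' pair of a CpG emits its two positions separately.
    """
    fh.write('track type=wiggle_0 name="cytosine_methylation"\n')
    chrom = None
    for s in sites:
        if s.chrom != chrom:
            fh.write(f"variableStep chrom={s.chrom}\n")
            chrom = s.chrom
        fh.write(f"{s.pos + 1}\t{s.level:.4f}\n")


def write_meth_outputs(sites: List[CytosineSite], formats: Iterable[str],
                       paths: Dict[str, str],
                       split_contexts: bool = False) -> List[str]:
    """Write methylation outputs in the requested formats.

    ``paths`` maps format name ('tab', 'bed', 'wig') to an output path.
    With ``split_contexts`` one file per context class is written, the
    context tag inserted before the extension.
    """
    writers = {"tab": write_tab, "bed": write_bed, "wig": write_wig}
    written: List[str] = []
    for fmt in formats:
        if fmt not in writers:
            raise ValueError(f"unknown methylation output format {fmt!r}")
        if split_contexts:
            for ctx in CONTEXTS:
                path = _context_path(paths[fmt], ctx)
                with open(path, "w") as fh:
                    writers[fmt]([s for s in sites if s.context == ctx], fh)
                written.append(path)
        else:
            with open(paths[fmt], "w") as fh:
                writers[fmt](sites, fh)
            written.append(paths[fmt])
    return written


def _context_path(path: str, ctx: str) -> str:
    if "." in path.rsplit("/", 1)[-1]:
        stem, ext = path.rsplit(".", 1)
        return f"{stem}.{ctx}.{ext}"
    return f"{path}.{ctx}"
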