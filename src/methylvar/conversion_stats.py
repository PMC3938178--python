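"""Bisulfite conversion-rate estimation and the binomial test for
conversion error.

The conversion rate is estimated from reads aligned to a fully
unmethylated control genome (lambda phage, chloroplast): every cytosine
call on the matching bisulfite strand is either converted (T on OT reads,
A on OB reads) or unconverted (C / G), and the rate is
converted / (converted + unconverted).

Given a bisulfite failure rate ``p`` (= 1 - conversion rate), the test
asks how probable it is that more than ``fmc`` of the ``mc`` observed
methylcytosines at a site are conversion failures, where ``fmc`` is the
largest number of false methylcytosines that keeps the methylation level
within a chosen error interval of the observed level:

    p_value = 1 - sum_{k=0}^{fmc} C(mc, k) p^k (1-p)^(mc-k)

A small p-value means the observed level is unlikely to be off by more
than the interval through conversion failure alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .alignments_io import BASE_INDEX, BisRead, PileupMatrix
from .methylation import CytosineSite


@dataclass
class ConversionRateReport:
    rate: float
    converted: int
    unconverted: int
    per_context: Dict[str, Tuple[int, int]]  # context -> (converted, unconv)

    @property
    def failure_rate(self) -> float:
        return 1.0 - self.rate


@dataclass
class MethTest:
    site: CytosineSite
    mc: int
    cov: int
    interval: float
    fmc: int
    p: float  # bisulfite failure rate (1 - conversion rate)
    p_value: float
    q_value: Optional[float] = None
    significant: Optional[bool] = None


def estimate_conversion_rate(reads: Iterable[BisRead],
                             control_ref: Dict[str, str],
                             minQ: int = 20) -> ConversionRateReport:
    """Estimate the conversion rate over all cytosines of both strands of a
    fully unmethylated control genome."""
    from .methylation import assign_context

    per_chrom: Dict[str, PileupMatrix] = {}
    for read in reads:
        if read.chrom not in control_ref:
            continue
        mat = per_chrom.get(read.chrom)
        if mat is None:
            mat = per_chrom[read.chrom] = PileupMatrix(
                read.chrom, control_ref[read.chrom], minQ)
        mat.add_read(read)
    iC, iG, iT, iA = (BASE_INDEX[b] for b in "CGTA")
    conv = unconv = 0
    per_context: Dict[str, List[int]] = {c: [0, 0] for c in ("CG", "CHG", "CHH")}
    for chrom, mat in per_chrom.items():
        ref = np.frombuffer(mat.ref_seq.encode(), dtype=np.uint8)
        for strand, cyt_code, s_idx, i_unconv, i_conv in (
                ("+", ord("C"), 0, iC, iT), ("-", ord("G"), 1, iG, iA)):
            positions = np.nonzero(ref == cyt_code)[0]
            u = mat.counts[positions, s_idx, i_unconv]
            c = mat.counts[positions, s_idx, i_conv]
            conv += int(c.sum())
            unconv += int(u.sum())
            covered = np.nonzero(u + c)[0]
            for k in covered:
                pos = int(positions[k])
                ctx = assign_context(mat.ref_seq, pos, strand)
                if ctx is not None:
                    per_context[ctx][0] += int(c[k])
                    per_context[ctx][1] += int(u[k])
    total = conv + unconv
    if total == 0:
        raise ValueError("no informative cytosine calls in control data")
    return ConversionRateReport(
        conv / total, conv, unconv,
        {k: (v[0], v[1]) for k, v in per_context.items()})


def max_false_mc(mc: int, cov: int, interval: float) -> int:
    """Largest number f of false methylcytosines with
    (mc - f)/cov still within ``interval`` of mc/cov:
    f = min(mc, floor(interval * cov))."""
    if cov <= 0:
        raise ValueError("cov must be > 0")
    if not 0 <= mc <= cov:
        raise ValueError("mc must lie in [0, cov]")
    if not 0.0 <= interval <= 1.0:
        raise ValueError("interval must lie in [0, 1]")
    return min(mc, math.floor(interval * cov + 1e-9))


def meth_pvalue(mc: int, fmc: int, p: float) -> float:
    """Probability of more than ``fmc`` conversion failures among ``mc``
    observed methylcytosines: the binomial survival function at fmc."""
    if not 0 <= fmc <= mc:
        raise ValueError("fmc must lie in [0, mc]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if mc == 0:
        return 0.0
    return float(binom.sf(fmc, mc, p))


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (q_values, significance flags)."""
    pv = np.asarray(p_values, dtype=float)
    if pv.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(pv, alpha=alpha, method="fdr_bh")
    return q, reject


def run_meth_tests(sites: Sequence[CytosineSite], failure_rate: float,
               interval: float, fdr_alpha: Optional[float] = None
               ) -> List[MethTest]:
    """Run the conversion-error test on profiled sites.

    Sites with mc = 0 have p_value 0 by convention (no false
    methylcytosines are possible).  When ``fdr_alpha`` is given, BH
    q-values and significance flags are attached.
    """
    tests: List[MethTest] = []
    for s in sites:
        fmc = max_false_mc(s.mc_count, s.cov, interval)
        pv = meth_pvalue(s.mc_count, fmc, failure_rate)
        tests.append(MethTest(s, s.mc_count, s.cov, interval, fmc,
                              failure_rate, pv))
    if fdr_alpha is not None and tests:
        q, flags = bh_fdr([t.p_value for t in tests], fdr_alpha)
        for t, qv, fl in zip(tests, q, flags):
            t.q_value = float(qv)
            t.significant = bool(fl)
    return tests
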