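# Methods

## Scope and data model

`methylvar` consumes a reference genome (FASTA) and coordinate-sorted
alignments of bisulfite-treated reads (SAM/BAM) and produces per-cytosine
methylation profiles and SNV calls in one pass. It does not align reads,
recalibrate qualities or realign indels. Internally all coordinates are
0-based half-open; 1-based coordinates appear only in the output writers
(native tab, WIG, VCF).

Every retained read carries a bisulfite-strand label: OT (the read derives
from the original top/'+' genomic strand) or OB (original bottom). A
Bismark-style `XG:Z:CT`/`XG:Z:GA` tag takes precedence; without a tag the
FLAG reverse bit decides, which assumes a directional library. If tag and
FLAG contradict each other the tag wins and a warning is logged.
Unmapped, secondary and supplementary records are skipped. Paired-end
mates are treated as independent reads; overlapping mates can double-count
a position, a known limitation worth remembering for high-coverage
paired-end data. Insertions relative to the reference contribute nothing
to any column, deleted reference positions receive no contribution, and
positions where the reference is N are never profiled or tested.

## Read-level filters

* **5' trimming** (`trim5`, default 0; use 3 for MspI sites of
  non-directional RRBS): removes bases from the *sequencing* 5' end, which
  for a reverse-aligned read is its rightmost aligned base — the start
  coordinate then stays put and the right end is clipped.
* **Duplicate selection** (off by default, since external duplicate
  markers may already have been applied): reads grouped by (contig, start,
  bisulfite strand) and by their high-quality seed — the bases among the
  first `seedLen` (26) from the sequencing 5' end with quality ≥ `minQ` —
  are considered clonal; per seed group the read with most quality-passing
  bases survives, ties go to the longer read, remaining ties to a
  seeded-uniform pick. Keying on the seed keeps co-starting reads that
  carry different alleles. Strand is part of the key because reads from
  opposite original strands are never clones of one molecule.
* **Bisulfite-failure filter** (on by default): a read is dropped when at
  least `bisFailureFrac` (90%) of its quality-passing non-CpG-context
  cytosine positions read as unconverted. No minimum count of such
  positions is imposed beyond n > 0; the threshold is conservative enough
  that ordinary reads are essentially never lost. The filter should be
  disabled for samples with substantial genuine non-CpG methylation
  (plants, embryonic stem cells) — the CLI warns accordingly.

## Methylation profiling

For a '+'-strand cytosine only OT reads are informative: `mc` = C calls,
converted = T calls, `cov = mc + converted`, level = `mc/cov`. ('-'
cytosines mirror this with OB reads and G/A calls in SAM orientation.)
A/G calls at a '+' cytosine are evidence of variation, not of conversion
state, and are excluded from the ratio. Context (CG, CHG, CHH; H = A/C/T)
is read off the reference 5'→3' on the cytosine's own strand; a cytosine
whose two downstream bases run off the contig gets no context and is not
reported. Context comes from the reference, not the inferred genotype.
Sites need `minDepthMeth` (default 3) informative calls; the mean PHRED of
counted calls is reported to 2 decimals. The two cytosines of a CpG are
separate records.

SNV feedback: a site whose called genotype removes the cytosine on both
chromosomes is suppressed (no cytosine exists in the sample); a
heterozygous genotype is kept but flagged in an extra column so
allele-biased levels can be treated separately downstream.

## SNV calling

Conversion destroys part of the evidence: a T call on an OT read may be a
converted C, an A call on an OB read may be a converted G. These calls are
discarded everywhere before allele counting; the remaining counts are
summed across strands. This conservative rule is applied at every
position, including A/T reference sites where in principle both strands
could be used as in ordinary resequencing — the cost is some sensitivity
at heterozygous sites whose alternate allele is only visible on one
strand (measured on simulations: overall sensitivity in the high-80s
rather than the low-90s percent at 20×).

Candidates are non-reference alleles with usable frequency ≥ `varFraction`
(0.1) at usable depth ≥ `minDepthSNV` (1). Significance uses a one-sided
Fisher exact test of `[[n_ref, n_var], [round(N(1−e)), round(N·e)]]` with
e = `snvErrRate` (0.01): the observed split against the split expected if
every non-reference call were a sequencing error. The exact 2×2 table is
a design choice — the frequency-then-Fisher scheme follows VarScan, and
the implementation is verified against exhaustive hypergeometric
enumeration to 1e-12 for all depths ≤ 50. Calls require p < `maxPval`
(0.05); the genotype is the two highest-count alleles among {reference} ∪
candidates, homozygous when the runner-up falls below `varFraction`, with
ties broken on the fixed order A<C<G<T for determinism. VCF output encodes
GT/AD per sample and QUAL = −10·log₁₀(p) capped at 255.

## Conversion rate and the binomial error test

The conversion rate is estimated from alignments to a fully unmethylated
control genome as converted/(converted + unconverted) over all cytosines
of both strands (OT: T vs C; OB: A vs G), quality-gated like everything
else, with per-context subtotals reported.

Given failure rate p = 1 − conversion rate, a site with `mc` observed
methylcytosines and coverage `cov` tolerates
`fmc = min(mc, ⌊interval·cov⌋)` false methylcytosines before its level
leaves the error interval (boundary inclusive); the closed form is
verified against brute force. The p-value `1 − BinomCDF(fmc; mc, p)` is
computed with scipy's survival function (log-space stable) and verified
against direct term-by-term summation to 1e-12 up to mc = 200 (property
tests go to 300). Sites with mc = 0 get p-value 0 by convention: no false
methylcytosine is possible. The test addresses methylation *levels*, not
binary states — intermediate levels (allele-specific methylation, partial
methylation) are first-class. Benjamini–Hochberg q-values (delegated to
statsmodels, verified against a hand-rolled step-up oracle) are optional
and off by default.

## Synthetic data generator

The generator emulates a WGBS experiment with known truth:

* **Genome:** i.i.d. random sequence, GC 0.42 (typical mammalian bulk
  value). Real genomes have CpG islands and repeats; the simulator does
  not, so results on it say nothing about mapping artifacts or regional
  composition effects — only about the extraction statistics.
* **Diploid variants:** planted at density 10⁻³/bp (half heterozygous,
  alt allele uniform among the three alternatives), the default matching
  the benchmark conditions used throughout.
* **Methylation:** preset per dataset — all CpG cytosines methylated or
  all unmethylated, non-CpG cytosines always unmethylated; states are
  computed per haplotype, so a variant that destroys a CpG in one
  haplotype yields a genuine intermediate truth level of 0.5.
* **Reads:** drawn uniformly from both haplotypes and both original
  strands at the target mean coverage (default 20×, read length 100);
  each unmethylated cytosine on the read's strand converts with
  probability `conv_rate` (default 0.99); sequencing errors hit each base
  with probability 10^(−Q/10).
* **Qualities:** `q30` (constant Q30, the default) or `mixed`, a
  heavy-tailed mix (Q8/Q12/Q25/Q38 at 8/7/15/70%) standing in for the
  miscalibrated tail of real replayed quality strings; the mixed model is
  what makes minQ sweeps informative, since with constant Q30 every
  threshold ≤ 30 admits every call.
* Alignments are emitted truth-perfect (no aligner), isolating the
  extraction statistics from mapping artifacts.

Evaluation: an SNV call is a true positive only when its genotype matches
the planted genotype exactly; sensitivity is TP over all planted variants
and the false-positive fraction is 1 − precision. Methylation accuracy is
the fraction of profiled cytosines whose level equals the simulated truth
*exactly*, evaluated only where both haplotypes retain the cytosine
(variant sites are the SNV caller's jurisdiction).

## Problem sizes and numerical choices

The benchmark runs in the test suite and `scripts/acceptance.py` use a
1 Mb genome for the SNV regime (≈1000 planted variants — large enough
that sensitivity is estimated to about ±1 point), 250 kb for the
mixed-quality minQ sweep and 100 kb for conversion-rate recovery and the
zero-noise identity check; these sizes were chosen as the smallest at
which the sampling noise of each metric is well below the effects being
demonstrated. Control-genome simulations for conversion-rate estimation
disable sequencing errors: the estimator deliberately measures conversion
failure and sequencing error jointly (as it would on real data), so
isolating the conversion parameter requires error-free reads.

All randomness flows through a single seeded NumPy generator per run;
reruns with the same inputs and seed are byte-identical, including the
random tie-break in duplicate selection (candidates are canonically
ordered before the draw, so the choice is independent of input order).

## Known limitations

* No overlap-aware handling of read pairs.
* No indel calling, and indel-containing alignments contribute only their
  aligned bases.
* Genotype-aware context correction (a C→T het changing a neighbour's
  context) is not attempted.
* The methylation/SNV feedback acts per position; multi-nucleotide events
  are out of scope.
* The simulator's uniform alt-allele choice yields slightly harder
  variant classes than transition-biased real SNP catalogues; measured
  sensitivities on it are accordingly a little conservative.
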