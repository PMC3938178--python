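# methylvar

Per-cytosine methylation profiling and single-nucleotide variant (SNV)
calling from aligned whole-genome bisulfite sequencing (WGBS) reads, in one
program.

## The problem

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected, so the C/T composition of
aligned reads encodes the methylation level of every cytosine. Getting
that level right requires controlling several error sources that most
extraction tools ignore:

* **Sequence variants.** A C→T SNV looks exactly like an unmethylated
  cytosine. On the complementary strand, however, the variant appears as an
  A/G mismatch that bisulfite conversion cannot produce — so variants are
  detectable, and must be, or methylation levels at those sites are wrong.
* **Clonal reads.** PCR duplicates bias coverage; but two co-starting reads
  may carry two alleles, so duplicates are recognised by start coordinate
  *plus* a high-quality 5' seed, not coordinates alone.
* **Bisulfite conversion failure.** Reads in which nearly all
  non-CpG-context cytosines stay unconverted signal a failed molecule and
  are dropped.
* **Sequencing errors.** Every base call is gated on a minimum PHRED score
  `minQ` (default 20).

`methylvar` profiles every covered reference cytosine on both strands
(CG / CHG / CHH context, methylcytosine count `mc`, informative coverage
`cov`, level `mc/cov`, mean base quality), calls SNVs with a strand-aware
adaptation of the VarScan scheme, and writes tab/BED/WIG methylation
tables plus a VCF of variants.

## The statistics

**SNV calling.** At each position the usable allele counts exclude calls
confounded by conversion (T on reads from the original top strand, A on
reads from the original bottom strand). Non-reference alleles with
relative frequency ≥ `varFraction` (default 0.1) at usable depth ≥
`minDepthSNV` (default 1) are candidates; the observed ref/variant split
(n_ref, n_var) out of N usable calls is tested one-sided by Fisher's exact
test against the split expected from sequencing error alone,

```
[[ n_ref, n_var ], [ round(N(1−e)), round(N·e) ]],   e = 0.01,
```

and positions with p < `maxPval` (default 0.05) are genotyped from the two
highest-frequency alleles.

**Conversion-error test.** With the bisulfite failure rate
p = 1 − conversion rate (estimated from an unmethylated control genome
such as lambda phage), a site with `mc` observed methylcytosines gets

```
p-value = 1 − Σ_{k=0}^{fmc} C(mc, k) p^k (1−p)^(mc−k),
fmc = min(mc, ⌊interval · cov⌋),
```

the probability that more than `fmc` of the observed methylcytosines are
conversion failures — i.e. that the true methylation level lies outside
the chosen error interval of the observed one. Example: 21 reads with 17
methylcytosines (level 0.81) tolerate `fmc` = 2 false methylcytosines at
interval 0.1, and the p-value at p = 0.01 is 6.12 × 10⁻⁴. Optional
Benjamini–Hochberg FDR control is available.

## Worked example

Simulate a small dataset with known truth, then analyse it:

```
$ methylvar simulate --length 20000 --coverage 20 --seed 11 --out-prefix sim
$ methylvar run sim.fa sim.sam --out-prefix out --meth-formats tab,bed,wig
... INFO methylvar: profiled 8302 cytosines, called 15 SNVs
$ head -3 out.meth.tsv
#chrom	pos	strand	context	mc	cov	mean_qual	level
sim1	24	+	CHG	0	3	30.00	0.00
sim1	25	+	CG	3	3	30.00	1.00
$ grep -c -v '^#' out.snv.vcf
15
```

Each methylation row is one cytosine: 1-based position, strand, sequence
context, methylcytosine count, informative coverage, mean PHRED of the
counted calls, and the methylation level `mc/cov` (the default simulation
preset methylates every CpG, so the CG site reads 1.00 and the CHG site
0.00). Heterozygous sites
carry a ninth genotype column; cytosines lost homozygously to a variant
are suppressed from the table. The VCF reports each variant's genotype
(GT), usable allelic depths (AD) and Fisher-test quality.

The auxiliary subcommands mirror the two control-experiment steps:
`methylvar convrate control.fa control.sam` estimates the conversion rate
from an unmethylated control, and `methylvar methtest out.meth.tsv
--conversion-rate 0.99 --interval 0.1 --out tested.tsv` appends the
`fmc`/p-value columns.

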