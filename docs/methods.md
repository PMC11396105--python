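# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions.

## Coordinates and formats

VCF and GFF3 are 1-based inclusive on disk; all in-memory intervals are
0-based half-open, converted once in the readers (`read_vcf`, `read_gff3`,
`read_cx_report` keeps the 1-based `pos` column of CX reports and converts
at use sites). Gene regions are strand-aware: `upstream2kb` is the 2 kb 5'
of the TSS on the gene's strand, `downstream2kb` the 2 kb 3' of the TES.

## Diagnostic SNP selection

Hard filter: a site passes iff **not** (QD < 2.0 or FS > 60.0 or MQ < 40.0)
and every parent's GQ >= 20. The inequalities are strict, so boundary values
(QD = 2.0, FS = 60.0, MQ = 40.0, GQ = 20) pass. Missing annotations fail the
filter (conservative) and are tallied. Multi-allelic sites are skipped with
a logged count — the homozygous-divergent pattern presupposes biallelic
sites. Parental genotypes are treated as unphased; `0/0 x 1/1` is read as a
homozygosity pattern, not phasing. Gene assignment is exonic-only (RNA reads
cover exons); a SNP in an exon overlap of two genes is assigned to both and
flagged ambiguous rather than dropped.

## Reciprocal best hits

Hits with e-value > 1e-5 are removed; "best" is the highest bitscore with
ties broken by smaller e-value then lexicographic subject id, making the
matching deterministic. The output is injective both ways.

## Allelic bias test

Per gene, paternal and maternal counts are summed over diagnostic SNPs per
replicate. Significance: two-sided exact binomial test of the paternal count
against p = 1/2; BH across genes. Classification gates:

* ratio gate — paternal:maternal ratio >= 2 in **every** replicate
  (maternal: <= 0.5). `mat = 0` with `pat > 0` gives ratio = +inf (gate
  satisfied); no pseudocounts, which would silently shift ratios.
* significance gate — q <= 0.01. Default `q_mode="pooled"`: one test on
  replicate-summed counts per gene, BH across genes. The strict alternative
  `q_mode="per_replicate"` requires every replicate to reach q <= 0.01
  individually. The pooled default was chosen because (a) replicate RNA
  libraries in this study design are pooled before sequencing, so one
  gene-level q matches the data-generating process, and (b) the strict mode
  has materially lower power: with BH at q <= 0.01 over a few hundred genes
  the effective per-replicate p threshold is ~3e-3, which caps 3-replicate
  sensitivity near 0.89 at 60 informative reads per replicate and 4-fold
  bias, whereas the pooled mode reaches ~0.95 with the same ~0 false-call
  rate (the triple ratio gate alone has null probability ~1e-7).
* coverage gate — any replicate total below `min_total` (default 10) flags
  the gene low-coverage and leaves it unclassified: a dominance call from a
  handful of reads is not defensible. The threshold is a package convention,
  exposed as a parameter.

## Methylation

Methylcytosine calling: one-sided binomial test of count_M against the
bisulfite non-conversion error (default 0.01), BH across sites, methylated
iff q <= 0.05; zero-coverage sites are flagged unevaluated, not tested.

Levels are always coverage-weighted pooled ratios sum(M)/sum(M+U);
a region with no covered site has no level rather than level 0.

DMRs: the genome is tiled with fixed, non-overlapping 200-bp windows
anchored at coordinate 0 (the simplest reproducible choice; the window and
step are configurable). Sites need coverage >= 4 in **both** groups to be
eligible. Per window, the two groups' eligible counts are pooled into a 2x2
table and compared with a two-sided Fisher exact test — exact, assumes no
within-group replication, and identical in spirit to the default two-group
logic of the standard window-based DMR callers. BH is applied per context
across all tested windows genome-wide. A window is a DMR iff q <= 0.05,
|delta| >= the context threshold and it holds at least the context's minimum
number of eligible cytosines (CG/CHG: 5 and 0.25; CHH: 15 and 0.15;
all-context: 20 and 0.20). Opposite-strand CG sites are kept separate by
default (lossless); `merge_cg_strands=True` collapses symmetric CpGs.

DMCs use the same machinery per site; the screening thresholds (coverage
>= 4 both groups, |delta| >= 0.25, q <= 0.05 per context) are an explicit
package convention, exposed as parameters.

DMR-gene association: a gene is a DMG iff at least one DMR overlaps
(half-open) its gene body or +/- 2 kb flanks; one output row per
(gene, region, DMR).

## Expression

FPKM = count x 1e9 / (gene length x library size); library sizes default to
column sums. The differential test is a deliberately simple stand-in for a
full GLM-based package: median-of-ratios size factors (total-count fallback
when geometric means vanish), tagwise method-of-moments NB dispersion
shrunk 50:50 toward the median dispersion with a 0.01 floor, log2 fold
change on normalised group means with a 0.5 pseudocount (avoids
infinities), and a Wald test from the delta-method variance of the log
mean. Externally computed DEG tables (`gene_id, log2fc, padj`) are accepted
by every downstream step, so the test is swappable; the test suite
cross-checks it against an independent NB implementation (pydeseq2) on
simulated data, where the called DEG sets agree almost exactly. DEG status
uses padj < 0.05 and |log2FC| >= 1; log2FC is hybrid over maternal.

## Integration

Expression bins on the RPKM scale: non (<= 1), low (1, 10], middle
(10, 100], high (> 100) — half-open exactly as conventionally printed.
The methylation-expression relationship is computed gene-wise (per-gene
expression vs per-gene region level, Spearman), the strictest testable
pairing; per-bin mean levels are reported descriptively. In the DEG-DMG
intersection each overlapping DMR yields one record (multi-hit flagged when
one region carries DMRs of both directions, which real loci do), and the
region's consensus direction is the sign of the mean delta. Quadrants map
(up, hyper) -> E+M+, (up, hypo) -> E+M-, (down, hyper) -> E-M+,
(down, hypo) -> E-M-.

## Synthetic cross

What it emulates: two diverged parental gene sets with homozygous-divergent
exonic SNPs (Poisson mean 5 per gene — roughly the diagnostic-site density
of a ~0.5% diverged exome over 1-2 kb genes); hybrid allele-informative RNA
reads per gene and replicate ~ Poisson(60), split multinomially across the
gene's SNPs and binomially between alleles at p = fold/(fold+1) with
fold = 4 for planted biased genes (15% paternal, 15% maternal by default);
per-cytosine methylation counts at coverage ~ Poisson(20) with vertebrate-
like baselines (CG 0.8, CHG/CHH 0.02) and planted CG DMRs shifted by -0.5
(hypomethylated in the hybrid — the baseline is too high for a +0.5 shift)
in one 200-bp tile per chosen gene; negative-binomial counts (dispersion
0.1) with 30% planted DEGs at |log2FC| = 2. Genes sit 50 per
pseudo-chromosome, non-overlapping, strands alternating, with one cytosine
site every 10 bp cycling CG/CHG/CHH across the gene body and 2 kb flanks.

What it does not emulate — and hence what passing tests do not show about
real data: read-level artefacts (mapping bias toward the reference allele,
bisulfite conversion failure, M-bias), linkage between SNPs, overdispersed
or spatially autocorrelated methylation, tissue structure, and sequence
content (FASTA outputs are placeholders). Recovery rates on this generator
measure the statistical machinery, not robustness to alignment artefacts.

All randomness flows from a single seed; each output file uses a substream
keyed by a stable label (CRC of the name), so outputs are byte-identical
under a fixed config and independent of generation order.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 200 genes
(about 110k cytosine sites, 23k tested windows) and the null methylome at
100 genes (about 11k windows), sizes at which every stage completes in
seconds while leaving thousands of windows/genes for rate estimates.

## Known limitations

No replicate-aware beta-binomial DMR model (groups are pooled); no
mapping-bias correction for ASE; the DEG test is a simplified NB Wald test,
not a full GLM with shrinkage; DMC screening thresholds are a convention,
as the field has no single standard.
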