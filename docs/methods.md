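# Methods

`apatrend` analyses alternative polyadenylation (APA) from 3'-end
sequencing of two libraries (typically a tumour/normal pair without
replicates). This note describes the model and procedure each module
implements, the parameters that matter, what the synthetic data emulate,
and the numerical and design choices made where the method left room.

## Data model and coordinates

All coordinates are 0-based half-open internally; BED input is native and
the minimal GTF dialect is converted on read. A gene is the union of
transcripts sharing a `gene_id`. The gene's UTR anchor — the origin of the
3'-UTR length axis — is the 3'-most annotated stop-codon boundary
(`cds_end`) among the gene's transcripts, and the UTR length of a cleavage
position is the strand-aware distance from the anchor, minimum 1 nt. When a
gene has several annotated transcript ends, the per-transcript ends are
kept for site-tier annotation and collapsed only at the gene level for the
length axis.

## Read cleaning (preprocess)

3'-end reads from oligo-dT priming begin with the complement of the polyA
tail, so cleaning is three-stage:

- quality filter: mean Phred >= `min_mean_q` (default 20) and N fraction
  <= `max_n_frac` (default 0.1). No specific cutoff is canonical for this
  protocol; 20/0.1 are the conventional defaults and both are configurable.
- polyNT filter: a read is discarded when its longest single-base run
  covers >= `max_homopolymer_frac` (default 0.8) of its length. The
  qualitative notion of "polyNT" artefacts (runs of one base, mostly T) is
  made operational as this run-fraction rule.
- poly-T trim: the 5' run of T (>= `min_t_run`, default 8, tolerating <= 1
  non-T per 10 nt of run so one sequencing error does not discard a read)
  is removed; the remainder must be >= 25 nt to remain uniquely mappable.

Reads are not reverse-complemented here: orientation is the aligner's job,
and site calling interprets alignment strand.

## Site calling (sitecall)

The cleavage position of an alignment is its strand-aware 3' terminus
(rightmost aligned base on `+`, leftmost on `-`). Only unique alignments
are used (NH tag when present, else MAPQ > 3).

**Internal-priming filter.** Oligo-dT can prime on A-rich genomic sequence
instead of a polyA tail. An event is removed when the 20-nt genomic window
immediately downstream (transcription direction; reverse-complemented on
`-`) contains >= 12 A in total, a contiguous `AAAAAAAA`, or matches
`G A{4,} G A{3,} G`. The 12-A rule is read as ">= 12 of 20"; the G/A
pattern string is read with `+` as one-or-more of the preceding base, the
only self-consistent reading. Windows truncated at contig ends are
evaluated as-is, without padding.

**Clustering.** Events from both samples are pooled and single-linkage
chained per (chromosome, strand): sorted by position, a new cluster starts
when the gap to the previous event exceeds 24 nt. This gap rule (rather
than fixed windows) matches the pairwise "within 24 nt" notion and is
invariant to input order. Clusters with fewer than 2 pooled reads are
discarded; the representative position is the position with the highest
pooled count, ties resolved to the 3'-most. Per-sample counts are kept.

**Annotation.** Tier priority: a site within 24 nt (absolute genomic
distance, same strand) of an annotated transcript end is tier `UCSC`; else
within 24 nt of a known-site DB record, `TianDB`; else `novel`. Genomic
region uses the priority `UTR3 > CDS > intron > noncoding > downstream1k
(<= 1000 nt past the transcript end) > intergenic`; exonic positions 5' of
the 3' UTR are folded into `CDS` since the vocabulary has no separate 5'
class. The owning gene is the gene of the matched end or overlapped
region; an exactly equidistant transcript-end tie goes to the 5'-side gene.

## Tandem-UTR switch test (apaswitch)

For each gene with >= 2 tandem sites in admissible regions (`UTR3`,
`downstream1k`), reads form a 2 x k table: columns are sites ordered by
UTR length Y_1 < ... < Y_k, row one is sample one, row two sample two.
Each read is an observation (X, Y), X in {1, 2} the sample index, Y its
site's UTR length in nt (not the site rank). The switch index is the
Pearson correlation

    TSI = r = cov(X, Y) / (sigma_X sigma_Y)

computed from count-weighted moments (identical to the expanded per-read
correlation). The trend statistic M^2 = (n - 1) r^2 is referred to the
chi-square distribution with 1 degree of freedom; direction comes from
sign(r): r > 0 means sample two's reads sit at longer UTRs (lengthening),
r < 0 shortening. Genes are excluded, with a recorded reason, when they
have < 2 usable sites, zero reads in either sample row (the
expressed-in-both requirement, applied before the read cut), fewer than 30
total reads, or a degenerate marginal (all reads in one sample or at one
site). BH FDR is computed over tested genes only; calls require |r| > 0.1
and FDR < 0.01. No continuity correction is applied to M^2.

Useful invariances: r is antisymmetric under swapping the sample rows and
invariant under positive affine maps of Y (but not under general monotone
maps — the statistic uses the metric UTR lengths).

## Differential expression (expression)

A 3'-end protocol samples one tag per transcript, so gene counts need no
length normalisation. For a gene with x reads out of N1 in library one and
y out of N2 in library two, equal expression implies, conditional on the
pooled total t = x + y,

    x | t ~ Binomial(t, N1 / (N1 + N2)),

the exact conditional two-library test (the normalisation of the
Audic-Claverie kernel (N2/N1)^y (x+y)!/(x! y! (1+N2/N1)^(x+y)) over x at
fixed total). Conditioning on the total makes the test exactly symmetric
under exchanging the libraries, bit-for-bit in this implementation because
each tail is evaluated in its own library's orientation. The two-sided p
doubles the smaller tail, capped at 1; tails are regularised
incomplete-beta evaluations, stable for counts >= 10^6. Being exact and
discrete, the test is mildly conservative at small totals.

Fold change is log2(((y+0.5)/N2)/((x+0.5)/N1)) — the 0.5 pseudocount
appears only in the fold, never in the test — positive when higher in
sample two. Calls require FDR < 0.01 and |log2FC| >= 1 on the normalised
scale. Library totals N1, N2 default to reads surviving the
internal-priming filter, the last filter before counting.

The qPCR helper `ddct_ratio` converts paired cUTR/eUTR Ct values to
2^-ddCt, the relative change in extended-UTR product between conditions
(ratio > 1 = relatively more distal product in condition b).

## Enrichment (enrich)

Fold enrichment of a gene set is (k/n)/(K/N) for k list hits among n list
genes versus K population hits among N background genes. The p-value is
the EASE score: the upper-tail hypergeometric probability with one list
hit removed (k = 1 is never significant); a plain Fisher variant is
available (`penalize=False`). The background is always the genes testable
in the run, never a hard-coded universe. BH adjustment shares the exact
code path used by the switch and expression stages.

## Synthetic data (simdata)

The generator builds a toy chromosome of non-overlapping single-exon genes
on both strands (300 nt body = 60 nt 5' UTR + 240 nt CDS, separated by
300-nt intergenic gaps), each with 2-4 tandem polyA sites 60-120 nt apart
starting 80-150 nt past the stop codon. The distal site coincides with the
annotated transcript end (exercising the `UCSC` tier); exactly half of the
non-distal sites are registered in the known-site DB (`TianDB` tier), the
rest are `novel`.

Per library (default 100,000 reads), gene totals are multinomial over
lognormal(mu=4, sigma=1) expression weights; within a gene, site counts
are multinomial over the planted usage vector. Default fractions: 10%
of genes shortened and 10% lengthened (proximal fraction 0.8 <-> 0.2
between samples, remaining mass Dirichlet over the other sites), 10% up-
and 10% down-regulated at 4-fold. A read is a 8-18 nt poly-T run plus the
reverse complement of the <= 50 nt of transcript upstream of the cleavage
position; cleavage jitter is Normal(0, 5 nt) rounded and truncated at
+/- 17 nt, so sites spaced >= 60 nt can never merge under the 24-nt gap
rule (60 - 2*17 = 26 > 24). Reads are emitted both as FASTQ (for the
cleaning stage) and as pre-aligned BED — the default analysis route, since
alignment is an external step.

Internal-priming decoys are planted as 20-nt A-runs (T-runs on `-`) in
intergenic gaps; decoy reads (2% of depth) sit exactly at the decoy
position, so they fail the filter by construction. Conversely the
neighbourhood of every true site (+/- jitter plus the 20-nt window) is
rewritten with sequence carrying at most 1 A-or-T per 5-nt block, so no
true read can be filtered on either strand. Optional labelled junk reads
(low quality, polyNT) exercise the cleaning stage with known truth.

What the generator does not emulate: sequencing errors beyond quality
strings, PCR duplicates, multi-mapping, introns, overlapping genes,
replicates, or biological covariance between switching and expression.
Passing recovery tests therefore demonstrates correctness of the
computational chain under the stated sampling model, not robustness to
every artefact of real libraries.

## Calibration and verification choices

- The TSI implementation is checked against brute-force Pearson on the
  expanded per-read vectors (1e-12 relative, 1,000 random tables).
- The chi-square p of M^2 is compared with a 10,000-rep exact-margin
  permutation null on tables of 200-500 reads. The permutation null of
  |r| is discrete; ties at the observed value are counted half (mid-p).
  Agreement is asserted within the 99.9% binomial Monte-Carlo envelope
  plus an allowance of 0.03 for the residual asymptotic error, sized from
  a pilot at these table sizes (k = 2 tables with a heavy tie atom are
  the binding case).
- Type-I error of the trend test is measured on 5,000 null genes (both
  rows one multinomial, 30-300 reads) at p < 0.05 against the binomial
  99% CI.
- Recovery uses the generator at its default study conditions; the strong-
  shift benchmark (0.8 -> 0.2 proximal, 200-500 reads/table) expects
  >= 95% sign-correct calls and <= 5% empirical FDR at FDR < 0.01.
- The exact-conditional expression test is verified against termwise
  direct summation of the conditional mass (1e-10 relative) and for exact
  library-exchange symmetry; its null calibration is measured at realistic
  per-gene depth (lognormal around 400 reads, matching millions of reads
  over ~15k genes).
- Analysis drivers run at 200 genes and 100k reads per library; these
  sizes give every stage hundreds of events per decision without
  obscuring the arithmetic.

## Known limitations

- Single-pair design: no dispersion estimation; the exact conditional test
  treats biological variability as zero, as any no-replicate test must.
- Region classification assumes transcript models with correct thick
  (CDS) annotation; single-exon synthetic models do not exercise deep
  intron logic.
- The trend test uses metric UTR lengths; genes whose site spacing is
  extremely skewed can be dominated by one distal site.
- The generator's usage shifts are planted on the proximal site only;
  k-site redistribution patterns beyond proximal<->distal are not
  simulated.
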