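# apatrend

Tandem 3'-UTR (alternative polyadenylation) analysis from 3'-end
sequencing reads, for transcriptomics researchers comparing polyA-site
usage between two libraries — typically a tumour/normal pair sequenced
with an oligo-dT-primed 3'-end protocol (SAPAS-style).

The pipeline goes from aligned 3'-end reads to:

1. **polyA sites** — strand-aware cleavage positions, an internal-priming
   filter (events whose 20-nt downstream genomic window holds >= 12 A, an
   `AAAAAAAA` 8-mer, or `G A{4,} G A{3,} G` are artefacts), 24-nt
   single-linkage clustering, a >= 2-read support rule, and annotation
   against transcript ends and a known-site database.
2. **switch calls** — per gene, reads form a 2 x k count table over the
   tandem sites ordered by 3'-UTR length; the tandem APA switch index is
   the count-weighted Pearson correlation between sample index X in {1,2}
   and UTR length Y,

       TSI = r = cov(X, Y) / (sigma_X sigma_Y),     M^2 = (n - 1) r^2,

   with M^2 referred to chi-square (1 df). Genes with |TSI| > 0.1 and
   BH FDR < 0.01 are called: TSI < 0 = 3' UTR shortened in sample two.
   Tables with < 30 reads are excluded.
3. **differential expression** — the exact conditional two-library test
   (x | x+y ~ Binomial(x+y, N1/(N1+N2)), the Audic-Claverie-style tag
   count test), FDR < 0.01 and two-fold normalised change.
4. **gene-set enrichment** — fold enrichment (k/n)/(K/N) and the EASE
   one-tailed hypergeometric score on user-supplied GMT sets.

A fully ground-truthed synthetic-data generator (`apatrend.simdata`)
emulates two libraries of poly-T reads with cleavage jitter, planted
proximal/distal usage shifts, expression fold changes and A-rich
internal-priming decoys, so every stage is testable end to end without an
external aligner. See `docs/methods.md` for the model details.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic
experiment (200 genes, 100,000 reads per library, seed 42; 10% of genes
shortened, 10% lengthened, 10% up- and 10% down-regulated at 4-fold) and
write tables under `results/`:

```
$ python analysis/01_simulate.py
genes: 200  tandem sites: 562  decoy loci: 6
switch labels: {'null': 160, 'shortened': 20, 'lengthened': 20}

$ python analysis/03_call_sites.py
events: 200000  internal-priming filtered: 4000  sites: 562
tiers: {'novel': 181, 'UCSC': 200, 'TianDB': 181}
regions: {'UTR3': 474, 'downstream1k': 88}

$ python analysis/04_switch_test.py
genes with tandem tables: 200  tested: 200
calls: {'none': 160, 'shortened': 20, 'lengthened': 20}
  G0062: TSI=+0.608 n=4186 M2=1549.1 fdr=0.00e+00 -> lengthened
  G0151: TSI=-0.507 n=7994 M2=2054.9 fdr=0.00e+00 -> shortened

$ python analysis/07_score_recovery.py
site sensitivity: 1.000  mean positional error: 1.57 nt
empirical FDR among switch calls: 0.000
switch confusion (planted -> called): {'null->none': 160,
  'shortened->shortened': 20, 'lengthened->lengthened': 20}
```

All 4,000 filtered events are the planted internal-priming decoys (2% of
each library); all 562 planted sites are recovered, every planted switch
is called with the correct sign, and no null gene is called. The same
stages are available as a CLI (`apatrend simulate / preprocess / sites /
run-all / enrich`) and as plain library calls (`apatrend.sitecall`,
`apatrend.apaswitch`, ...).

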