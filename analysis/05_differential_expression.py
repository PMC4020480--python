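"""Differential gene expression between the two libraries.

Gene counts (reads on called sites) are compared with the exact
conditional two-library test; calls require FDR < 0.01 and a two-fold
normalised change.  Positive log2 fold change = higher in sample two.
"""

from collections import Counter

from _common import RESULTS, SAMPLES, called_sites

from apatrend.expression import call_degs, degs_to_frame, gene_counts_from_sites


def main() -> None:
    sites, kept, _ = called_sites()
    n1 = sum(1 for e in kept if e.sample_id == SAMPLES[0])
    n2 = sum(1 for e in kept if e.sample_id == SAMPLES[1])
    gene_counts = gene_counts_from_sites(sites, SAMPLES, n1, n2)
    results = call_degs(gene_counts)
    RESULTS.mkdir(exist_ok=True)
    degs_to_frame(results).to_csv(RESULTS / "dge.tsv", sep="\t", index=False)

    print(f"library totals: {n1} / {n2}  genes tested: {len(results)}")
    print("calls:", dict(Counter(r.call for r in results)))
    top = sorted((r for r in results if r.call != "none"), key=lambda r: r.fdr)[:5]
    for r in top:
        print(f"  {r.gene_id}: {r.x} vs {r.y} reads, log2FC={r.log2fc:+.2f} "
              f"fdr={r.fdr:.2e} -> {r.call}")


if __name__ == "__main__":
    main()
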