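"""Gene-set enrichment of the called gene lists.

Fold enrichment ((k/n)/(K/N)) and the EASE one-tailed over-representation
p-value against the background of all genes tested in this run; the
generator planted the shortened genes inside one gene set, which should
surface at the top.
"""

from _common import RESULTS, SAMPLES, called_sites, dataset

from apatrend.apaswitch import switch_analysis
from apatrend.enrich import enrich_list, enrichment_to_frame
from apatrend.expression import call_degs, gene_counts_from_sites


def main() -> None:
    ref, _ = dataset()
    sites, kept, _ = called_sites()
    switch_results, _ = switch_analysis(sites, ref.transcripts, SAMPLES)
    gene_counts = gene_counts_from_sites(sites, SAMPLES)
    deg_results = call_degs(gene_counts)
    background = [gc.gene_id for gc in gene_counts]
    RESULTS.mkdir(exist_ok=True)

    lists = {
        "shortened": [r.gene_id for r in switch_results if r.call == "shortened"],
        "lengthened": [r.gene_id for r in switch_results if r.call == "lengthened"],
        "down": [r.gene_id for r in deg_results if r.call == "down"],
    }
    for name, genes in lists.items():
        rows = enrich_list(genes, ref.gene_sets, background)
        enrichment_to_frame(rows).to_csv(RESULTS / f"enrich_{name}.tsv", sep="\t", index=False)
        print(f"{name}: {len(genes)} genes, {len(rows)} sets with hits")
        for r in rows[:2]:
            print(f"  {r.set_id}: {r.list_hits}/{r.list_size} vs {r.pop_hits}/{r.pop_size} "
                  f"fold={r.fold:.2f} p={r.p:.2e} fdr={r.fdr:.2e}")


if __name__ == "__main__":
    main()
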