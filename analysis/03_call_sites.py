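"""Call polyA sites from the aligned reads.

Cleavage events are the strand-aware 3' termini of the alignments; events
whose 20-nt downstream genomic window is A-rich (internal-priming decoys)
are removed, the rest are clustered with the 24-nt gap rule, and clusters
with >= 2 pooled reads become sites, annotated by tier (known transcript
end / known-site DB / novel) and genomic region.
"""

from collections import Counter

from _common import RESULTS, SAMPLES, called_sites, dataset

from apatrend.sitecall import sites_to_frame, summarize_run, write_sites_bed


def main() -> None:
    ref, sim = dataset()
    sites, kept, filtered = called_sites()
    RESULTS.mkdir(exist_ok=True)

    sites_to_frame(sites, list(SAMPLES)).to_csv(RESULTS / "site_counts.tsv", sep="\t", index=False)
    write_sites_bed(str(RESULTS / "sites.bed"), sites)

    stage_counts = {}
    for sample, events in zip(SAMPLES, (sim.events1, sim.events2)):
        n_raw = len(events)
        n_pass = sum(1 for e in kept if e.sample_id == sample)
        stage_counts[sample] = {"raw": n_raw, "ip_pass": n_pass}
    summarize_run(stage_counts).to_csv(RESULTS / "run_summary.tsv", sep="\t", index=False)

    print(f"events: {len(kept) + len(filtered)}  "
          f"internal-priming filtered: {len(filtered)}  sites: {len(sites)}")
    print("tiers:", dict(Counter(s.tier for s in sites)))
    print("regions:", dict(Counter(s.region for s in sites)))
    genes_with_sites = {s.gene_id for s in sites if s.gene_id}
    print(f"genes with called sites: {len(genes_with_sites)} / {len(ref.truth.genes)}")


if __name__ == "__main__":
    main()
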