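"""Generate the synthetic two-library 3'-end sequencing experiment.

Writes the toy genome, transcript models, known-site DB, gene sets, two
FASTQ + pre-aligned BED libraries and the ground-truth tables, and reports
what was planted.
"""

from _common import CONFIG, RESULTS, SCRATCH, dataset

from apatrend.simdata import truth_frame, write_dataset


def main() -> None:
    ref, sim = dataset()
    RESULTS.mkdir(exist_ok=True)
    paths = write_dataset(ref, sim, SCRATCH)
    truth = truth_frame(ref.truth)
    truth.to_csv(RESULTS / "truth_genes.tsv", sep="\t", index=False)

    n_sites = sum(len(g.site_positions) for g in ref.truth.genes.values())
    print(f"genes: {CONFIG.n_genes}  tandem sites: {n_sites}  "
          f"decoy loci: {len(ref.truth.decoy_positions)}")
    print("switch labels:", truth.switch_label.value_counts().to_dict())
    print("expression labels:", truth.deg_label.value_counts().to_dict())
    print(f"reads per library: {CONFIG.depth} (jitter sd {CONFIG.jitter_sd} nt, "
          f"decoy rate {CONFIG.decoy_rate})")
    print("dataset written to", SCRATCH)


if __name__ == "__main__":
    main()
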