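"""Clean the raw FASTQ libraries: quality filter, polyNT filter, poly-T trim.

The oligo-dT complement at each read's 5' end is the evidence the read
comes from a polyadenylated 3' terminus; reads without it are discarded.
"""

import pandas as pd
from _common import RESULTS, SAMPLES, dataset

from apatrend.preprocess import preprocess_reads


def main() -> None:
    _, sim = dataset()
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for sample, reads in zip(SAMPLES, (sim.reads1, sim.reads2)):
        kept, audit, counts = preprocess_reads(reads)
        reasons = pd.Series([r for _, r in audit]).value_counts().to_dict()
        rows.append({"sample": sample, **counts, **reasons})
        frac = counts["polyT_pass"] / counts["raw"]
        print(f"{sample}: {counts['raw']} raw -> {counts['polyT_pass']} "
              f"clean poly-T reads ({100 * frac:.1f}%), drops: {reasons}")
    pd.DataFrame(rows).to_csv(RESULTS / "preprocess_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
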