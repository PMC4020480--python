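"""Shared setup for the numbered analysis drivers.

All drivers analyse one deterministic synthetic two-library experiment
(200 genes, 100k reads per library, seed 42) emulating a tumour/normal
3'-end sequencing pair: sample one plays the normal tissue, sample two the
tumour.  Heavy per-read artefacts (FASTQ/BED) live under scratch/; summary
tables under results/.
"""

from functools import lru_cache
from pathlib import Path

from apatrend import sitecall
from apatrend.simdata import SimConfig, make_reference, simulate_reads

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "dataset"

CONFIG = SimConfig(
    n_genes=200,
    depth=100_000,
    seed=42,
    low_quality_rate=0.02,
    polynt_rate=0.01,
)
SAMPLES = ("sample1", "sample2")


@lru_cache(maxsize=1)
def dataset():
    ref = make_reference(CONFIG)
    sim = simulate_reads(ref, CONFIG)
    return ref, sim


@lru_cache(maxsize=1)
def called_sites():
    """Internal-priming-filtered, clustered, annotated polyA sites."""
    ref, sim = dataset()
    events = sim.events1 + sim.events2
    kept, filtered = sitecall.internal_priming_filter(events, ref.genome)
    sites = sitecall.annotate_sites(
        sitecall.cluster_events(kept), ref.transcripts, ref.known_db
    )
    return sites, kept, filtered
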