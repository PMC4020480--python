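"""End-to-end orchestration: alignments -> sites -> switch + DGE -> enrichment.

A run is a pure function of (inputs, config, seed): outputs are written as
tab-separated tables plus a JSON manifest echoing every threshold, so
repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import apaswitch, enrich, expression, refio, sitecall


@dataclass
class RunConfig:
    """Every stage threshold, explicit; defaults are the analysis defaults."""

    genome: str = ""
    transcripts: str = ""
    known_sites: str = ""
    gmt: str = ""
    alignments: tuple[str, str] = ("", "")  # sample one, sample two (row order)
    sample_labels: tuple[str, str] = ("sample1", "sample2")
    cluster_gap: int = sitecall.CLUSTER_GAP
    annot_tol: int = sitecall.ANNOT_TOL
    ip_window: int = sitecall.IP_WINDOW
    ip_min_a: int = sitecall.IP_MIN_A
    min_site_reads: int = 2
    min_table_reads: int = apaswitch.MIN_READS
    r_cut: float = apaswitch.R_CUT
    switch_fdr_cut: float = apaswitch.FDR_CUT
    deg_fdr_cut: float = expression.FDR_CUT
    fold_cut: float = expression.FOLD_CUT
    ease_penalize: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, counts: dict | None = None):
        super().__init__(f"[{stage}] {message} (counts so far: {counts or {}})")
        self.stage = stage
        self.counts = counts or {}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run sitecall -> switch + expression -> enrichment and write results.

    Returns a summary dict (also written as manifest.json) with per-stage
    counts in the run-summary layout.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    for label, path in (("genome", config.genome), ("transcripts", config.transcripts)):
        if not Path(path).exists():
            raise PipelineError("inputs", f"missing {label} file: {path}", counts)

    genome = refio.read_genome(config.genome)
    transcripts = refio.read_transcripts(config.transcripts, genome)
    known_db = (
        refio.read_known_sites(config.known_sites, genome)
        if config.known_sites and Path(config.known_sites).exists()
        else refio.KnownSiteDB([])
    )

    s1, s2 = config.sample_labels
    events = []
    for label, path in zip(config.sample_labels, config.alignments):
        if not Path(path).exists():
            raise PipelineError("sitecall", f"missing alignment file: {path}", counts)
        ev = sitecall.extract_cleavage(path, label)
        counts[f"events_{label}"] = len(ev)
        events.extend(ev)

    kept, filtered = sitecall.internal_priming_filter(
        events, genome, config.ip_window, config.ip_min_a
    )
    counts["internal_priming_filtered"] = len(filtered)
    counts["ip_pass"] = len(kept)
    sites = sitecall.annotate_sites(
        sitecall.cluster_events(kept, config.cluster_gap, config.min_site_reads),
        transcripts,
        known_db,
        config.annot_tol,
    )
    counts["sites"] = len(sites)
    sitecall.write_sites_bed(str(outdir / "sites.bed"), sites)
    sitecall.sites_to_frame(sites, list(config.sample_labels)).to_csv(
        outdir / "site_counts.tsv", sep="\t", index=False
    )

    switch_results, tables = apaswitch.switch_analysis(
        sites,
        transcripts,
        config.sample_labels,
        config.r_cut,
        config.switch_fdr_cut,
        config.min_table_reads,
    )
    counts["genes_tested_switch"] = sum(1 for r in switch_results if not r.excluded)
    counts["switch_calls"] = sum(
        1 for r in switch_results if r.call in ("shortened", "lengthened")
    )
    apaswitch.results_to_frame(switch_results, tables).to_csv(
        outdir / "switch.tsv", sep="\t", index=False
    )

    n1 = sum(1 for e in kept if e.sample_id == s1)
    n2 = sum(1 for e in kept if e.sample_id == s2)
    gene_counts = expression.gene_counts_from_sites(sites, config.sample_labels, n1, n2)
    deg_results = expression.call_degs(gene_counts, config.deg_fdr_cut, config.fold_cut)
    counts["genes_tested_dge"] = len(deg_results)
    counts["degs"] = sum(1 for r in deg_results if r.call != "none")
    expression.degs_to_frame(deg_results).to_csv(outdir / "dge.tsv", sep="\t", index=False)

    enrich_rows = {}
    if config.gmt and Path(config.gmt).exists():
        sets = refio.read_gmt(config.gmt)
        background = [gc.gene_id for gc in gene_counts]
        lists = {
            "shortened": [r.gene_id for r in switch_results if r.call == "shortened"],
            "lengthened": [r.gene_id for r in switch_results if r.call == "lengthened"],
            "up": [r.gene_id for r in deg_results if r.call == "up"],
            "down": [r.gene_id for r in deg_results if r.call == "down"],
        }
        for name, genes in lists.items():
            rows = enrich.enrich_list(genes, sets, background, config.ease_penalize)
            enrich_rows[name] = rows
            enrich.enrichment_to_frame(rows).to_csv(
                outdir / f"enrich_{name}.tsv", sep="\t", index=False
            )
            counts[f"enriched_sets_{name}"] = len(rows)

    manifest = {
        "config": _jsonable(asdict(config)),
        "counts": counts,
        "manifest_hash": "",
    }
    payload = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(payload).hexdigest()[:16]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "counts": counts,
        "sites": sites,
        "switch_results": switch_results,
        "deg_results": deg_results,
        "enrichment": enrich_rows,
        "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
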