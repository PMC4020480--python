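"""From unique alignments to annotated polyA sites.

The stages, in order: extract each read's strand-aware 3' terminus (the
inferred cleavage position); drop events whose 20-nt downstream genomic
window looks like an oligo-dT internal-priming target (A-rich rules);
single-linkage cluster the surviving events with a 24-nt gap rule, keeping
clusters supported by at least two pooled reads; annotate each cluster
against transcript ends (tier "UCSC"), a known-site database (tier
"TianDB") or as novel, and classify its genomic region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .refio import FormatError, GenomeRef, KnownSiteDB, TranscriptModel, gene_anchors

IP_WINDOW = 20
IP_MIN_A = 12
IP_EIGHT_A = "AAAAAAAA"
IP_G_PATTERN = re.compile(r"GA{4,}GA{3,}G")
CLUSTER_GAP = 24
ANNOT_TOL = 24
DOWNSTREAM_EXT = 1000

TIERS = ("UCSC", "TianDB", "novel")
REGIONS = ("UTR3", "CDS", "intron", "noncoding", "downstream1k", "intergenic")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CleavageEvent:
    chrom: str
    strand: str
    pos: int  # genomic coordinate of the read's 3'-most aligned base
    sample_id: str


@dataclass
class PolyASite:
    chrom: str
    strand: str
    pos: int  # representative position: pooled-count mode of the cluster
    counts: dict[str, int]
    tier: str | None = None
    region: str | None = None
    gene_id: str | None = None
    positions: dict[int, int] = field(default_factory=dict)  # pos -> pooled count

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def extract_cleavage(
    path: str,
    sample_id: str,
    unique_only: bool = True,
    fmt: str | None = None,
) -> list[CleavageEvent]:
    """Extract cleavage events from a SAM/BAM or BED6 alignment file.

    The cleavage position is the 3'-most aligned base: the rightmost base on
    '+', the leftmost on '-'.  With ``unique_only`` multi-mappers are dropped
    using the NH tag when present, else MAPQ > 3; unmapped records are
    skipped.
    """
    if fmt is None:
        fmt = "bed" if path.endswith(".bed") else "sam"
    if fmt == "bed":
        return _extract_from_bed(path, sample_id)
    return _extract_from_sam(path, sample_id, unique_only)


def _extract_from_bed(path: str, sample_id: str) -> list[CleavageEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path} line {lineno}: BED6 needs 6 fields")
            chrom, start, end, _name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            pos = end - 1 if strand == "+" else start
            events.append(CleavageEvent(chrom, strand, pos, sample_id))
    return events


def _extract_from_sam(path: str, sample_id: str, unique_only: bool) -> list[CleavageEvent]:
    import pysam

    events = []
    skipped_unmapped = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped_unmapped += 1
                continue
            if unique_only:
                if aln.has_tag("NH"):
                    if aln.get_tag("NH") > 1:
                        continue
                elif aln.mapping_quality <= 3:
                    continue
            strand = "-" if aln.is_reverse else "+"
            pos = aln.reference_end - 1 if strand == "+" else aln.reference_start
            events.append(CleavageEvent(aln.reference_name, strand, pos, sample_id))
    return events


def downstream_window(event: CleavageEvent, genome: GenomeRef, window: int = IP_WINDOW) -> str:
    """The ``window``-nt genomic sequence immediately downstream of the
    cleavage position in transcription direction, reverse-complemented on
    '-' so it reads 5'->3' along the transcript.  Truncated at contig ends.
    """
    if event.strand == "+":
        return genome.fetch(event.chrom, event.pos + 1, event.pos + 1 + window)
    return revcomp(genome.fetch(event.chrom, event.pos - window, event.pos))


def is_internal_priming(window: str, min_a: int = IP_MIN_A) -> bool:
    """A-rich rules: >= ``min_a`` A in total, a contiguous A 8-mer, or the
    G/A pattern G A{4,} G A{3,} G anywhere in the window."""
    return (
        window.count("A") >= min_a
        or IP_EIGHT_A in window
        or IP_G_PATTERN.search(window) is not None
    )


def internal_priming_filter(
    events: list[CleavageEvent],
    genome: GenomeRef,
    window: int = IP_WINDOW,
    min_a: int = IP_MIN_A,
) -> tuple[list[CleavageEvent], list[CleavageEvent]]:
    """Split events into (kept, filtered) by the downstream-window rules."""
    kept, filtered = [], []
    for ev in events:
        if is_internal_priming(downstream_window(ev, genome, window), min_a):
            filtered.append(ev)
        else:
            kept.append(ev)
    return kept, filtered


def cluster_events(
    events: list[CleavageEvent],
    gap: int = CLUSTER_GAP,
    min_reads: int = 2,
) -> list[PolyASite]:
    """Single-linkage chain events per (chrom, strand) with a gap rule.

    Events pooled over samples are sorted by position; a new cluster starts
    when the gap to the previous event exceeds ``gap`` nt.  Clusters with
    fewer than ``min_reads`` pooled reads are discarded.  The representative
    position is the position with the highest pooled count (tie: 3'-most).
    """
    by_key: dict[tuple[str, str], dict[int, dict[str, int]]] = {}
    samples: list[str] = []
    for ev in events:
        if ev.sample_id not in samples:
            samples.append(ev.sample_id)
        pos_counts = by_key.setdefault((ev.chrom, ev.strand), {})
        pos_counts.setdefault(ev.pos, {})
        pos_counts[ev.pos][ev.sample_id] = pos_counts[ev.pos].get(ev.sample_id, 0) + 1

    sites: list[PolyASite] = []
    for (chrom, strand), pos_counts in sorted(by_key.items()):
        positions = sorted(pos_counts)
        cluster: list[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > gap:
                sites.extend(_finish_cluster(chrom, strand, cluster, pos_counts, samples, min_reads))
                cluster = []
            cluster.append(pos)
        if cluster:
            sites.extend(_finish_cluster(chrom, strand, cluster, pos_counts, samples, min_reads))
    return sites


def _finish_cluster(
    chrom: str,
    strand: str,
    cluster: list[int],
    pos_counts: dict[int, dict[str, int]],
    samples: list[str],
    min_reads: int,
) -> list[PolyASite]:
    pooled = {p: sum(pos_counts[p].values()) for p in cluster}
    total = sum(pooled.values())
    if total < min_reads:
        return []
    best = max(pooled.values())
    candidates = [p for p in cluster if pooled[p] == best]
    rep = max(candidates) if strand == "+" else min(candidates)  # tie: 3'-most
    counts = {s: 0 for s in samples}
    for p in cluster:
        for s, c in pos_counts[p].items():
            counts[s] = counts.get(s, 0) + c
    return [PolyASite(chrom, strand, rep, counts, positions=pooled)]


def annotate_site(
    site: PolyASite,
    transcripts: list[TranscriptModel],
    known_db: KnownSiteDB,
    tol: int = ANNOT_TOL,
) -> PolyASite:
    """Assign tier, genomic-region class and owning gene to one site.

    Tier priority: within ``tol`` nt of a same-strand transcript end ->
    "UCSC"; else within ``tol`` of a same-strand known site -> "TianDB";
    else "novel".  Region priority: UTR3 > CDS > intron > noncoding >
    downstream1k > intergenic.  The owning gene is the gene of the matched
    transcript end or overlapped UTR; otherwise the nearest same-strand gene
    whose span (or 1-kb 3' extension) contains the position.  An equidistant
    transcript-end tie goes to the 5'-side gene.
    """
    same = [t for t in transcripts if t.chrom == site.chrom and t.strand == site.strand]
    pos = site.pos

    tier = "novel"
    gene_id: str | None = None
    tes_hits = [t for t in same if abs(pos - t.tes) <= tol]
    if tes_hits:
        tier = "UCSC"
        best = min(abs(pos - t.tes) for t in tes_hits)
        nearest = [t for t in tes_hits if abs(pos - t.tes) == best]
        if len(nearest) > 1:
            # equidistant tie: take the 5'-side gene (smaller tes on '+')
            nearest.sort(key=lambda t: t.tes, reverse=(site.strand == "-"))
        gene_id = nearest[0].gene_id
    else:
        for rec in known_db.records:
            if rec.chrom == site.chrom and rec.strand == site.strand and abs(pos - rec.pos) <= tol:
                tier = "TianDB"
                break

    region = "intergenic"
    region_gene: str | None = None
    best_rank = len(REGIONS)
    for t in same:
        r = _classify_region(pos, t)
        if r is None:
            continue
        rank = REGIONS.index(r)
        if rank < best_rank:
            best_rank, region, region_gene = rank, r, t.gene_id
    if gene_id is None:
        gene_id = region_gene
    return replace(site, tier=tier, region=region, gene_id=gene_id)


def _classify_region(pos: int, t: TranscriptModel) -> str | None:
    lo, hi = min(t.tx_start, t.tx_end), max(t.tx_start, t.tx_end)
    in_tx = lo <= pos < hi
    if in_tx and not t.coding:
        return "noncoding"
    if in_tx:
        u_lo, u_hi = (t.cds_end, t.tes) if t.strand == "+" else (t.tes, t.cds_end)
        if u_lo <= pos < u_hi:
            return "UTR3"
        if t.exons and not any(s <= pos < e for s, e in t.exons):
            return "intron"
        # exonic, 5' of the 3'-UTR: CDS (5'-UTR positions folded in here;
        # the region vocabulary has no separate class for them)
        return "CDS"
    if t.strand == "+" and t.tes <= pos < t.tes + DOWNSTREAM_EXT:
        return "downstream1k"
    if t.strand == "-" and t.tes - DOWNSTREAM_EXT < pos <= t.tes:
        return "downstream1k"
    return None


def annotate_sites(
    sites: list[PolyASite],
    transcripts: list[TranscriptModel],
    known_db: KnownSiteDB,
    tol: int = ANNOT_TOL,
) -> list[PolyASite]:
    return [annotate_site(s, transcripts, known_db, tol) for s in sites]


def call_sites(
    events: list[CleavageEvent],
    genome: GenomeRef,
    transcripts: list[TranscriptModel],
    known_db: KnownSiteDB,
    gap: int = CLUSTER_GAP,
    tol: int = ANNOT_TOL,
) -> tuple[list[PolyASite], dict[str, int]]:
    """Full site-calling stage; returns annotated sites and stage counts."""
    kept, filtered = internal_priming_filter(events, genome)
    sites = annotate_sites(cluster_events(events=kept, gap=gap), transcripts, known_db, tol)
    counts = {
        "events_in": len(events),
        "internal_priming_filtered": len(filtered),
        "events_kept": len(kept),
        "sites": len(sites),
    }
    return sites, counts


_SUMMARY_ROWS = (
    ("raw", "Raw reads"),
    ("clean", "Clean reads"),
    ("mapped", "Mapped to genome"),
    ("unique", "Uniquely mapped to genome"),
    ("nuclear", "Mapped to nuclear genome"),
    ("ip_pass", "Passed internal priming filter"),
)


def summarize_run(stage_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Per-sample run summary: read counts by stage with percent of raw.

    ``stage_counts`` maps sample -> {raw, clean, mapped, unique, nuclear,
    ip_pass, ...}; read stages must be monotone non-increasing.  Percentages
    are of raw reads, rounded to one decimal.  Extra keys (gene/site counts)
    are appended as plain counts.
    """
    rows = []
    for sample, counts in stage_counts.items():
        prev = None
        for key, _label in _SUMMARY_ROWS:
            if key not in counts:
                continue
            v = counts[key]
            if v < 0:
                raise ValueError(f"{sample}/{key}: negative count")
            if prev is not None and v > prev:
                raise ValueError(f"{sample}/{key}: stage counts must be non-increasing")
            prev = v
        raw = counts.get("raw")
        for key, label in _SUMMARY_ROWS:
            if key not in counts:
                continue
            pct = round(100.0 * counts[key] / raw, 1) if raw else None
            rows.append({"sample": sample, "stage": label, "count": counts[key], "pct_of_raw": pct})
        for key, v in counts.items():
            if key not in {k for k, _ in _SUMMARY_ROWS}:
                rows.append({"sample": sample, "stage": key, "count": v, "pct_of_raw": None})
    return pd.DataFrame(rows)


def sites_to_frame(sites: list[PolyASite], samples: list[str]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "chrom": s.chrom,
            "pos": s.pos,
            "strand": s.strand,
            "gene_id": s.gene_id or ".",
            "tier": s.tier,
            "region": s.region,
            "total": s.total,
        }
        for smp in samples:
            row[f"count_{smp}"] = s.counts.get(smp, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_sites_bed(path: str, sites: list[PolyASite]) -> None:
    """Sites as BED6+: name = gene|tier|region, score = pooled count."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            name = f"{s.gene_id or '.'}|{s.tier}|{s.region}"
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{name}\t{s.total}\t{s.strand}\n")
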