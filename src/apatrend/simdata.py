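"""Synthetic 3'-end sequencing data with ground truth for every stage.

The generator lays non-overlapping genes on a toy chromosome, plants 2-4
tandem polyA sites per gene at >= 60 nt spacing downstream of the stop
codon, and emits two libraries of oligo-dT-primed reads: a poly-T run
followed by the reverse complement of the transcript's 3' terminus, with
Gaussian cleavage jitter around the planted site.  Programmable fractions
of genes carry a proximal<->distal usage shift (3'-UTR shortening or
lengthening in sample two) and expression fold changes; A-rich
internal-priming decoy loci are planted in intergenic space, with decoy
reads guaranteed to fail the downstream-window filter.  Reads are written
both as FASTQ (to exercise the cleaning stage) and as pre-aligned BED (the
default route into site calling, since alignment is external).

Downstream windows of true sites are constructed with fewer than 8
consecutive and fewer than 12 total A, so true reads always survive the
internal-priming filter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .apaswitch import SwitchResult, TandemTable
from .expression import DEGResult
from .preprocess import ReadRecord
from .refio import (
    GeneSetCollection,
    GenomeRef,
    KnownSiteDB,
    KnownSiteRecord,
    TranscriptModel,
)
from .sitecall import CleavageEvent, PolyASite, revcomp

# jitter truncation: +/-17 nt keeps neighbouring 60-nt-spaced sites more
# than 24 nt apart after jitter (60 - 2*17 = 26), so planted sites cannot
# merge under the 24-nt cluster gap rule
JITTER_TRUNC = 17


@dataclass
class SimConfig:
    n_genes: int = 200
    sites_per_gene: tuple[int, int] = (2, 4)
    first_site_offset: tuple[int, int] = (80, 150)  # nt past the stop codon
    site_spacing: tuple[int, int] = (60, 120)  # nt between tandem sites
    frac_shortened: float = 0.1  # genes shifted toward proximal use in sample two
    frac_lengthened: float = 0.1
    shift_proximal: tuple[float, float] = (0.8, 0.2)  # sample-one, sample-two
    frac_up: float = 0.1  # genes with higher expression in sample two
    frac_down: float = 0.1
    expression_fold: float = 4.0
    lognormal_mu: float = 4.0
    lognormal_sigma: float = 1.0
    depth: int = 100_000  # reads per library
    jitter_sd: float = 5.0
    decoy_rate: float = 0.02  # fraction of each library from decoy loci
    n_decoy_loci: int = 6
    known_site_frac: float = 0.5  # planted sites registered in the known DB
    low_quality_rate: float = 0.0  # extra junk reads, labelled in read ids
    polynt_rate: float = 0.0
    intergenic_gap: int = 300
    seed: int = 0


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    anchor: int  # genomic cds_end
    site_positions: tuple[int, ...]  # proximal -> distal
    utr_lengths: tuple[int, ...]
    usage1: tuple[float, ...]
    usage2: tuple[float, ...]
    expr_weight1: float
    expr_weight2: float
    switch_label: str  # shortened | lengthened | null
    deg_label: str  # up | down | null
    counts1: tuple[int, ...] = ()
    counts2: tuple[int, ...] = ()


@dataclass
class SyntheticTruth:
    genes: dict[str, GeneTruth]
    decoy_positions: tuple[tuple[str, str, int], ...]  # (chrom, strand, pos)
    config: SimConfig


@dataclass
class Reference:
    genome: GenomeRef
    transcripts: list[TranscriptModel]
    known_db: KnownSiteDB
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


@dataclass
class SimReads:
    reads1: list[ReadRecord]
    reads2: list[ReadRecord]
    events1: list[CleavageEvent]
    events2: list[CleavageEvent]
    bed_rows1: list[tuple]
    bed_rows2: list[tuple]


def _safe_seq(rng: np.random.Generator, length: int) -> str:
    """Sequence with <= 1 A-or-T per 5-nt block, so on either strand a
    20-nt window holds <= 5 A, no A 8-mer and no G A{4,} G A{3,} G match
    (T is limited too because minus-strand windows are reverse
    complements)."""
    out = []
    for start in range(0, length, 5):
        block = list(rng.choice(list("CG"), size=min(5, length - start)))
        if len(block) == 5 and rng.random() < 0.7:
            block[rng.integers(0, 5)] = str(rng.choice(list("AT")))
        out.extend(block)
    return "".join(out)


def _usage_vectors(
    rng: np.random.Generator, k: int, label: str, shift: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    if label == "null":
        u = rng.dirichlet(np.full(k, 5.0))
        return u, u.copy()
    a, b = shift  # proximal fraction, sample one then sample two
    if label == "shortened":
        a, b = b, a  # sample two shifts toward the proximal site
    rest = rng.dirichlet(np.full(k - 1, 5.0))
    u1 = np.concatenate([[a], (1 - a) * rest])
    u2 = np.concatenate([[b], (1 - b) * rest])
    return u1, u2


def make_reference(config: SimConfig) -> Reference:
    """Build the toy genome, transcript models, known-site DB, gene sets
    and per-gene ground truth.  Fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chrom = "chrS"
    lo_s, hi_s = config.sites_per_gene
    if lo_s < 2:
        raise ValueError("sites_per_gene must start at 2")

    n = config.n_genes
    labels_switch = ["null"] * n
    labels_deg = ["null"] * n
    n_short = int(round(config.frac_shortened * n))
    n_long = int(round(config.frac_lengthened * n))
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    if n_short + n_long > n or n_up + n_down > n:
        raise ValueError("label fractions exceed the gene count")
    order = rng.permutation(n)
    for i in order[:n_short]:
        labels_switch[i] = "shortened"
    for i in order[n_short : n_short + n_long]:
        labels_switch[i] = "lengthened"
    order2 = rng.permutation(n)
    for i in order2[:n_up]:
        labels_deg[i] = "up"
    for i in order2[n_up : n_up + n_down]:
        labels_deg[i] = "down"

    base_expr = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)

    chrom_chars: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []
    known_candidates: list[KnownSiteRecord] = []
    genes: dict[str, GeneTruth] = {}
    decoy_positions: list[tuple[str, str, int]] = []
    safe_regions: list[tuple[int, int]] = []
    gap = config.intergenic_gap
    decoys_placed = 0

    for i in range(n):
        gene_id = f"G{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(lo_s, hi_s + 1))
        offsets = [int(rng.integers(*config.first_site_offset))]
        for _ in range(k - 1):
            offsets.append(offsets[-1] + int(rng.integers(*config.site_spacing)))
        utr_span = offsets[-1]
        body = 300  # 60 nt 5'UTR + 240 nt CDS
        total = body + utr_span

        # intergenic gap before the gene; plant a decoy locus in some gaps
        gap_seq = list(_intergenic_seq(rng, gap))
        if decoys_placed < config.n_decoy_loci and i % max(1, n // config.n_decoy_loci) == 0:
            d_local = gap // 2
            d_strand = "+" if rng.random() < 0.5 else "-"
            d_pos = cursor + d_local
            if d_strand == "+":
                gap_seq[d_local + 1 : d_local + 21] = "A" * 20
            else:
                gap_seq[d_local - 20 : d_local] = "T" * 20
            decoy_positions.append((chrom, d_strand, d_pos))
            decoys_placed += 1
        chrom_chars.extend(gap_seq)
        cursor += gap

        g_start = cursor
        chrom_chars.extend(_intergenic_seq(rng, total))
        if strand == "+":
            tx_start, tx_end = g_start, g_start + total
            cds_start, cds_end = g_start + 60, g_start + body
            site_pos = tuple(cds_end + o - 1 for o in offsets)
            tes = tx_end
        else:
            tx_start, tx_end = g_start, g_start + total
            cds_end, cds_start = g_start + utr_span, g_start + total - 60
            site_pos = tuple(cds_end - o for o in offsets)
            tes = tx_start

        # the tandem-site neighbourhood (sites +/- jitter plus their 20-nt
        # downstream windows, which for the distal site can reach into the
        # flanking intergenic gap) is rewritten later with A-limited
        # sequence so true reads always pass the internal-priming filter
        pad = JITTER_TRUNC + 25
        safe_regions.append((min(site_pos) - pad, max(site_pos) + pad))
        cursor += total

        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                cds_end=cds_end,
                tes=tes,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                exons=((tx_start, tx_end),),
                coding=True,
            )
        )
        # non-distal sites are candidates for the known DB (the distal site
        # already coincides with the annotated end)
        for j, p in enumerate(site_pos[:-1]):
            known_candidates.append(KnownSiteRecord(chrom, strand, p, f"{gene_id}_s{j}"))

        u1, u2 = _usage_vectors(rng, k, labels_switch[i], config.shift_proximal)
        w1 = base_expr[i]
        w2 = base_expr[i]
        if labels_deg[i] == "up":
            w2 *= config.expression_fold
        elif labels_deg[i] == "down":
            w2 /= config.expression_fold
        genes[gene_id] = GeneTruth(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            anchor=cds_end,
            site_positions=site_pos,
            utr_lengths=tuple(offsets),
            usage1=tuple(u1),
            usage2=tuple(u2),
            expr_weight1=w1,
            expr_weight2=w2,
            switch_label=labels_switch[i],
            deg_label=labels_deg[i],
        )

    chrom_chars.extend(_intergenic_seq(rng, gap))
    for lo, hi in safe_regions:
        lo, hi = max(lo, 0), min(hi, len(chrom_chars))
        chrom_chars[lo:hi] = _safe_seq(rng, hi - lo)
    genome = GenomeRef({chrom: "".join(chrom_chars)})

    # register exactly the configured fraction of candidate sites
    n_known = int(round(config.known_site_frac * len(known_candidates)))
    pick = rng.choice(len(known_candidates), size=n_known, replace=False)
    known = [known_candidates[i] for i in sorted(pick)]

    gene_sets = _make_gene_sets(rng, genes)
    truth = SyntheticTruth(genes, tuple(decoy_positions), config)
    return Reference(genome, transcripts, KnownSiteDB(known), gene_sets, truth)


def _intergenic_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=[0.22, 0.28, 0.28, 0.22]))


def _make_gene_sets(rng: np.random.Generator, genes: dict[str, GeneTruth]) -> GeneSetCollection:
    """A set enriched for shortened genes, one for lengthened, one for
    downregulated, plus random sets as an unenriched backdrop."""
    ids = sorted(genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}

    def padded(core: list[str], size: int) -> frozenset[str]:
        pool = [g for g in ids if g not in core]
        pad = list(rng.choice(pool, size=max(0, size - len(core)), replace=False))
        return frozenset(core + pad)

    short = [g for g in ids if genes[g].switch_label == "shortened"]
    long_ = [g for g in ids if genes[g].switch_label == "lengthened"]
    down = [g for g in ids if genes[g].deg_label == "down"]
    if short:
        sets["SET_SHORT"] = ("shortened-enriched pathway", padded(short, len(short) + 5))
    if long_:
        sets["SET_LONG"] = ("lengthened-enriched pathway", padded(long_, len(long_) + 5))
    if down:
        sets["SET_DOWN"] = ("down-enriched pathway", padded(down, len(down) + 5))
    for j in range(5):
        size = int(rng.integers(10, max(11, len(ids) // 4)))
        members = frozenset(rng.choice(ids, size=min(size, len(ids)), replace=False))
        sets[f"SET_RND{j}"] = (f"random set {j}", members)
    return GeneSetCollection(sets)


def _truncated_jitter(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    j = np.rint(rng.normal(0.0, sd, size=size)).astype(int)
    return np.clip(j, -JITTER_TRUNC, JITTER_TRUNC)


def simulate_reads(reference: Reference, config: SimConfig | None = None) -> SimReads:
    """Draw the two libraries and realise per-site counts into the truth.

    Per sample, gene read totals are multinomial over expression weights at
    the configured depth, then multinomial over planted site usage within
    each gene.  Decoy reads (a configured fraction of the depth) come from
    the planted A-rich loci with no jitter.  Junk reads (low quality,
    polyNT) are appended to the FASTQ only, labelled by read id.
    """
    if config is None:
        config = reference.truth.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    genome = reference.genome
    truth = reference.truth
    gene_ids = sorted(truth.genes)

    out = SimReads([], [], [], [], [], [])
    for s_idx, sample in enumerate(("sample1", "sample2")):
        weights = np.array(
            [
                truth.genes[g].expr_weight1 if s_idx == 0 else truth.genes[g].expr_weight2
                for g in gene_ids
            ]
        )
        n_decoy = int(round(config.decoy_rate * config.depth))
        n_real = config.depth - n_decoy
        gene_totals = rng.multinomial(n_real, weights / weights.sum())
        reads = out.reads1 if s_idx == 0 else out.reads2
        events = out.events1 if s_idx == 0 else out.events2
        bed = out.bed_rows1 if s_idx == 0 else out.bed_rows2

        for g, total in zip(gene_ids, gene_totals):
            gt = truth.genes[g]
            usage = np.array(gt.usage1 if s_idx == 0 else gt.usage2)
            site_counts = rng.multinomial(total, usage)
            if s_idx == 0:
                gt.counts1 = tuple(int(c) for c in site_counts)
            else:
                gt.counts2 = tuple(int(c) for c in site_counts)
            for j, (site, c) in enumerate(zip(gt.site_positions, site_counts)):
                if c == 0:
                    continue
                jit = _truncated_jitter(rng, config.jitter_sd, c)
                for m, dj in enumerate(jit):
                    pos = site + int(dj)
                    rid = f"r_{g}_s{j}_{sample}_{m}"
                    _emit_read(rid, gt.chrom, gt.strand, pos, sample, genome, rng, reads, events, bed)

        if truth.decoy_positions and n_decoy:
            picks = rng.integers(0, len(truth.decoy_positions), size=n_decoy)
            for m, pi in enumerate(picks):
                chrom, strand, pos = truth.decoy_positions[pi]
                rid = f"decoy_{sample}_{m}"
                _emit_read(rid, chrom, strand, pos, sample, genome, rng, reads, events, bed)

        for m in range(int(round(config.low_quality_rate * config.depth))):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            reads.append(ReadRecord(f"junk_lowq_{sample}_{m}", seq, chr(33 + 5) * 50))
        for m in range(int(round(config.polynt_rate * config.depth))):
            reads.append(ReadRecord(f"junk_polynt_{sample}_{m}", "T" * 50, "I" * 50))
    return out


def _emit_read(
    rid: str,
    chrom: str,
    strand: str,
    pos: int,
    sample: str,
    genome: GenomeRef,
    rng: np.random.Generator,
    reads: list[ReadRecord],
    events: list[CleavageEvent],
    bed: list[tuple],
) -> None:
    t_run = int(rng.integers(8, 19))
    if strand == "+":
        seg = genome.fetch(chrom, pos - 49, pos + 1)  # transcript 3' terminus
        body = revcomp(seg)
        start, end = pos - len(seg) + 1, pos + 1
    else:
        seg = genome.fetch(chrom, pos, pos + 50)
        body = seg  # revcomp of the minus-strand transcript terminus
        start, end = pos, pos + len(seg)
    seq = "T" * t_run + body
    reads.append(ReadRecord(rid, seq, "I" * len(seq)))
    events.append(CleavageEvent(chrom, strand, pos, sample))
    bed.append((chrom, start, end, rid, 0, strand))


def write_dataset(reference: Reference, sim: SimReads, outdir: str | Path) -> dict[str, str]:
    """Write FASTA/BED12/BED6/FASTQ/BED/GMT/truth/config files; returns paths."""
    from . import refio
    from .preprocess import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = outdir / "genome.fa"
    with open(p, "w") as fh:
        for chrom, seq in reference.genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = str(p)

    p = outdir / "transcripts.bed"
    with open(p, "w") as fh:
        for t in reference.transcripts:
            thick_start = t.cds_start if t.strand == "+" else t.cds_end
            thick_end = t.cds_end if t.strand == "+" else t.cds_start
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            offs = ",".join(str(s - t.tx_start) for s, e in t.exons) + ","
            fh.write(
                f"{t.chrom}\t{t.tx_start}\t{t.tx_end}\t{t.gene_id}\t0\t{t.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(t.exons)}\t{sizes}\t{offs}\n"
            )
    paths["transcripts"] = str(p)

    p = outdir / "known_sites.bed"
    refio.write_sites(str(p), reference.known_db)
    paths["known_sites"] = str(p)

    p = outdir / "gene_sets.gmt"
    refio.write_gmt(str(p), reference.gene_sets)
    paths["gene_sets"] = str(p)

    for sample, reads, rows in (
        ("sample1", sim.reads1, sim.bed_rows1),
        ("sample2", sim.reads2, sim.bed_rows2),
    ):
        p = outdir / f"{sample}.fastq"
        write_fastq(str(p), reads)
        paths[f"fastq_{sample}"] = str(p)
        p = outdir / f"{sample}.bed"
        with open(p, "w") as fh:
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        paths[f"bed_{sample}"] = str(p)

    p = outdir / "truth_genes.tsv"
    truth_frame(reference.truth).to_csv(p, sep="\t", index=False)
    paths["truth"] = str(p)

    p = outdir / "config.json"
    with open(p, "w") as fh:
        json.dump(asdict(reference.truth.config), fh, indent=1, default=list)
    paths["config"] = str(p)
    return paths


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    rows = []
    for g in sorted(truth.genes):
        gt = truth.genes[g]
        rows.append(
            {
                "gene_id": g,
                "chrom": gt.chrom,
                "strand": gt.strand,
                "anchor": gt.anchor,
                "site_positions": ",".join(map(str, gt.site_positions)),
                "utr_lengths": ",".join(map(str, gt.utr_lengths)),
                "usage1": ",".join(f"{u:.4f}" for u in gt.usage1),
                "usage2": ",".join(f"{u:.4f}" for u in gt.usage2),
                "expr_weight1": gt.expr_weight1,
                "expr_weight2": gt.expr_weight2,
                "switch_label": gt.switch_label,
                "deg_label": gt.deg_label,
                "counts1": ",".join(map(str, gt.counts1)),
                "counts2": ",".join(map(str, gt.counts2)),
            }
        )
    return pd.DataFrame(rows)


def simulate_tandem_tables(
    n_genes: int,
    reads_per_gene: int | tuple[int, int],
    usage1: tuple[float, ...],
    usage2: tuple[float, ...] | None,
    utr_lengths: tuple[int, ...],
    rng: np.random.Generator,
) -> list[TandemTable]:
    """Draw bare tandem tables (no genome) for statistical calibration.

    Each gene's two rows are independent multinomials at ``reads_per_gene``
    reads per sample (a range draws uniformly).  ``usage2=None`` means the
    null: both samples share ``usage1``.
    """
    u1 = np.asarray(usage1, dtype=float)
    u2 = u1 if usage2 is None else np.asarray(usage2, dtype=float)
    tables = []
    for i in range(n_genes):
        if isinstance(reads_per_gene, tuple):
            n_s = int(rng.integers(reads_per_gene[0], reads_per_gene[1] + 1))
        else:
            n_s = int(reads_per_gene)
        c1 = rng.multinomial(n_s, u1 / u1.sum())
        c2 = rng.multinomial(n_s, u2 / u2.sum())
        tables.append(TandemTable(f"sim{i}", tuple(utr_lengths), np.array([c1, c2], float)))
    return tables


def score_recovery(
    sites: list[PolyASite],
    switch_results: list[SwitchResult],
    deg_results: list[DEGResult],
    truth: SyntheticTruth,
    tol: int = 24,
) -> dict:
    """Compare pipeline output against planted truth.

    Returns site-level sensitivity and positional error, the switch-call
    confusion matrix by planted label, the DEG confusion matrix, and the
    empirical FDR among switch calls.
    """
    known_genes = set(truth.genes)
    for r in switch_results:
        if r.gene_id not in known_genes:
            raise ValueError(f"switch result for unknown gene {r.gene_id!r}")
    for r in deg_results:
        if r.gene_id not in known_genes:
            raise ValueError(f"DEG result for unknown gene {r.gene_id!r}")

    site_index: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        site_index.setdefault((s.chrom, s.strand), []).append(s.pos)
    n_truth = n_found = 0
    errors = []
    for gt in truth.genes.values():
        for p in gt.site_positions:
            n_truth += 1
            cand = site_index.get((gt.chrom, gt.strand), [])
            if cand:
                d = min(abs(c - p) for c in cand)
                if d <= tol:
                    n_found += 1
                    errors.append(d)

    switch_confusion: dict[tuple[str, str], int] = {}
    for r in switch_results:
        call = r.call if not r.excluded else "excluded"
        label = truth.genes[r.gene_id].switch_label
        switch_confusion[(label, call)] = switch_confusion.get((label, call), 0) + 1
    called = [r for r in switch_results if r.call in ("shortened", "lengthened")]
    false_calls = sum(1 for r in called if truth.genes[r.gene_id].switch_label == "null")
    wrong_sign = sum(
        1
        for r in called
        if truth.genes[r.gene_id].switch_label not in ("null", r.call)
    )

    deg_confusion: dict[tuple[str, str], int] = {}
    for r in deg_results:
        label = truth.genes[r.gene_id].deg_label
        deg_confusion[(label, r.call)] = deg_confusion.get((label, r.call), 0) + 1

    return {
        "site_sensitivity": n_found / n_truth if n_truth else float("nan"),
        "site_positional_error_mean": float(np.mean(errors)) if errors else float("nan"),
        "switch_confusion": switch_confusion,
        "switch_empirical_fdr": (false_calls + wrong_sign) / len(called) if called else 0.0,
        "deg_confusion": deg_confusion,
    }
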