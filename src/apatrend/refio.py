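"""Reference data model and readers/writers for the external formats.

All genomic coordinates are held 0-based half-open internally.  BED input is
native; the minimal GTF dialect is converted on read.  A "gene" is the union
of transcripts sharing a ``gene_id``; the gene-level 3'-UTR anchor (the point
UTR lengths are measured from) is derived downstream from the 3'-most
``cds_end`` among the gene's transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenomeRef:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the subsequence [start, end), truncated at chromosome ends."""
        seq = self.sequences[chrom]
        return seq[max(start, 0) : min(end, len(seq))]


@dataclass
class TranscriptModel:
    """One transcript with strand-aware 3'-UTR boundary coordinates.

    ``cds_end`` is the genomic coordinate of the stop codon's 3' boundary
    (the first UTR base on '+', one past the last UTR base on '-');
    ``tes`` is the annotated transcript end.  ``tx_start``/``tx_end``,
    ``cds_start`` and ``exons`` carry the full structure needed for
    genomic-region classification of polyA sites.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_end: int
    tes: int
    tx_start: int = 0
    tx_end: int = 0
    cds_start: int | None = None
    exons: tuple[tuple[int, int], ...] = ()
    coding: bool = True
    zero_length_utr: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.strand == "+" and self.cds_end > self.tes:
            raise FormatError(f"{self.gene_id}: cds_end > tes on + strand")
        if self.strand == "-" and self.cds_end < self.tes:
            raise FormatError(f"{self.gene_id}: cds_end < tes on - strand")
        if self.cds_end == self.tes:
            self.zero_length_utr = True


@dataclass(frozen=True)
class KnownSiteRecord:
    chrom: str
    strand: str
    pos: int
    source_id: str


@dataclass
class KnownSiteDB:
    """Single-base known polyA-site records, sorted by (chrom, pos)."""

    records: list[KnownSiteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos, r.strand))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Gene sets keyed by set id; each value is (display name, member set)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


def read_genome(path: str) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef` (sequences uppercased)."""
    sequences: dict[str, str] = {}
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        sequences[rec.id] = seq
    return GenomeRef(sequences)


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise FormatError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
    thick_start, thick_end = int(f[6]), int(f[7])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    coding = thick_start != thick_end
    if strand == "+":
        cds_end, tes = thick_end, end
    else:
        cds_end, tes = thick_start, start
    if not coding:
        # non-coding transcript: no UTR axis; anchor at the transcript end
        cds_end = tes
    return TranscriptModel(
        gene_id=name,
        chrom=chrom,
        strand=strand,
        cds_end=cds_end,
        tes=tes,
        tx_start=start,
        tx_end=end,
        cds_start=(thick_start if strand == "+" else thick_end) if coding else None,
        exons=exons,
        coding=coding,
    )


def _read_gtf(path: str) -> list[TranscriptModel]:
    # minimal dialect: CDS / exon / stop_codon / transcript features with
    # transcript_id "..." attributes; 1-based closed coordinates
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"line {lineno}: GTF needs 9 fields, got {len(f)}")
            chrom, _src, feat, start, end, _score, strand, _frame, attrs = f[:9]
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            tid = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("transcript_id"):
                    tid = chunk.split(None, 1)[1].strip('" ')
            if tid is None:
                raise FormatError(f"line {lineno}: missing transcript_id attribute")
            d = per_tx.setdefault(
                tid, {"chrom": chrom, "strand": strand, "exons": [], "cds": [], "stop": None, "tx": None}
            )
            if feat == "exon":
                d["exons"].append((start0, end0))
            elif feat == "CDS":
                d["cds"].append((start0, end0))
            elif feat == "stop_codon":
                d["stop"] = (start0, end0)
            elif feat == "transcript":
                d["tx"] = (start0, end0)

    out = []
    for tid, d in per_tx.items():
        strand = d["strand"]
        exons = tuple(sorted(d["exons"]))
        if d["tx"] is not None:
            tx_start, tx_end = d["tx"]
        elif exons:
            tx_start, tx_end = exons[0][0], exons[-1][1]
        else:
            raise FormatError(f"transcript {tid}: no exon or transcript feature")
        tes = tx_end if strand == "+" else tx_start
        flagged = False
        if d["stop"] is not None:
            cds_end = d["stop"][1] if strand == "+" else d["stop"][0]
        elif d["cds"]:
            # fall back to the 3'-most CDS boundary; flagged as derived
            cds = sorted(d["cds"])
            cds_end = cds[-1][1] if strand == "+" else cds[0][0]
            flagged = True
        else:
            cds_end = tes
        coding = bool(d["cds"]) or d["stop"] is not None
        cds_start = None
        if d["cds"]:
            cds = sorted(d["cds"])
            cds_start = cds[0][0] if strand == "+" else cds[-1][1]
        out.append(
            TranscriptModel(
                gene_id=tid,
                chrom=d["chrom"],
                strand=strand,
                cds_end=cds_end,
                tes=tes,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                exons=exons,
                coding=coding,
                flagged=flagged,
            )
        )
    return out


def read_transcripts(path: str, genome: GenomeRef | None = None) -> list[TranscriptModel]:
    """Read transcript models from BED12 or minimal GTF (by extension).

    Transcripts whose ``cds_end`` equals ``tes`` are retained but flagged as
    zero-length-UTR.  When a genome is supplied, coordinates are checked
    against chromosome bounds.
    """
    if path.endswith((".gtf", ".gff")):
        models = _read_gtf(path)
    else:
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                models.append(_parse_bed12_line(line, lineno))
    if genome is not None:
        lengths = genome.lengths
        for m in models:
            if m.chrom not in lengths or m.tx_end > lengths[m.chrom] or m.tx_start < 0:
                raise FormatError(
                    f"transcript {m.gene_id}: coordinates outside {m.chrom} bounds"
                )
    return models


def read_known_sites(path: str, genome: GenomeRef | None = None) -> KnownSiteDB:
    """Read a BED6 of single-base known polyA sites."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"line {lineno}: BED6 needs 6 fields, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if end - start != 1:
                raise FormatError(f"line {lineno}: known-site interval must be 1 base")
            if start < 0:
                raise FormatError(f"line {lineno}: negative coordinate {start}")
            if genome is not None and (
                chrom not in genome.sequences or end > len(genome.sequences[chrom])
            ):
                raise FormatError(f"line {lineno}: position outside {chrom} bounds")
            records.append(KnownSiteRecord(chrom, strand, start, name))
    return KnownSiteDB(records)


def write_sites(path: str, db: KnownSiteDB) -> None:
    """Write a KnownSiteDB back to single-base BED6."""
    with open(path, "w") as fh:
        for r in db.records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.source_id}\t0\t{r.strand}\n")


def read_gmt(path: str) -> GeneSetCollection:
    """Read gene sets from a tab-separated GMT file (id, name, members...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT line needs >=3 fields, got {len(f)}"
                )
            set_id, name, members = f[0], f[1], [m for m in f[2:] if m]
            if not members:
                raise FormatError(f"{path} line {lineno}: empty member list for {set_id}")
            uniq = frozenset(members)
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path} line {lineno}: duplicate members in set {set_id} deduplicated"
                )
            sets[set_id] = (name, uniq)
    return GeneSetCollection(sets)


def write_gmt(path: str, sets: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for sid, (name, members) in sets.sets.items():
            fh.write("\t".join([sid, name, *sorted(members)]) + "\n")


def gene_anchors(transcripts: Iterable[TranscriptModel]) -> dict[str, tuple[str, str, int, int]]:
    """Collapse transcripts to per-gene UTR anchors.

    Returns gene_id -> (chrom, strand, anchor, distal_tes) where ``anchor``
    is the 3'-most annotated ``cds_end`` among the gene's transcripts and
    ``distal_tes`` the 3'-most annotated end, both strand-aware.
    """
    out: dict[str, tuple[str, str, int, int]] = {}
    for t in transcripts:
        if t.gene_id not in out:
            out[t.gene_id] = (t.chrom, t.strand, t.cds_end, t.tes)
            continue
        chrom, strand, anchor, tes = out[t.gene_id]
        if strand == "+":
            out[t.gene_id] = (chrom, strand, max(anchor, t.cds_end), max(tes, t.tes))
        else:
            out[t.gene_id] = (chrom, strand, min(anchor, t.cds_end), min(tes, t.tes))
    return out
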