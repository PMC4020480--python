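"""FASTQ-level filtering applied before alignment.

Three stages mirror how 3'-end (oligo-dT primed) libraries are cleaned:
a mean-quality / N-content filter, a polyNT filter removing reads dominated
by a single-base run, and poly-T detection that trims the oligo-dT
complement off the 5' end and keeps only reads with enough remaining
sequence to map uniquely.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

DEFAULT_MIN_MEAN_Q = 20.0
DEFAULT_MAX_N_FRAC = 0.1
DEFAULT_MAX_HOMOPOLYMER_FRAC = 0.8
DEFAULT_MIN_T_RUN = 8
MIN_POST_TRIM_LENGTH = 25


@dataclass
class ReadRecord:
    id: str
    seq: str
    qual: str  # Phred+33 ASCII

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")

    @property
    def mean_quality(self) -> float:
        if not self.qual:
            return 0.0
        return sum(ord(c) - 33 for c in self.qual) / len(self.qual)

    @property
    def n_fraction(self) -> float:
        if not self.seq:
            return 0.0
        return self.seq.upper().count("N") / len(self.seq)


def _open(path: str, mode: str = "rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_fastq(path: str) -> Iterator[ReadRecord]:
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # '+'
            qual = fh.readline().strip()
            yield ReadRecord(header.strip()[1:].split()[0], seq, qual)


def write_fastq(path: str, reads: Iterable[ReadRecord]) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def longest_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def filter_quality(
    reads: Iterable[ReadRecord],
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Drop reads with mean Phred quality below ``min_mean_q`` or too many N.

    Returns (kept, dropped) where each dropped entry carries a reason tag,
    ``"mean_q"`` or ``"n_frac"`` (N content checked first).
    """
    kept, dropped = [], []
    for r in reads:
        if r.n_fraction > max_n_frac:
            dropped.append((r, "n_frac"))
        elif r.mean_quality < min_mean_q:
            dropped.append((r, "mean_q"))
        else:
            kept.append(r)
    return kept, dropped


def filter_polyNT(
    reads: Iterable[ReadRecord],
    max_homopolymer_frac: float = DEFAULT_MAX_HOMOPOLYMER_FRAC,
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Drop reads whose longest homopolymer run covers >= frac of the read."""
    kept, dropped = [], []
    for r in reads:
        if r.seq and longest_run(r.seq) >= max_homopolymer_frac * len(r.seq):
            dropped.append((r, "polyNT"))
        else:
            kept.append(r)
    return kept, dropped


def _leading_t_run(seq: str, min_t_run: int) -> int:
    """Length of the 5' poly-T run, tolerating <=1 non-T per 10 nt of run.

    The run is extended greedily; a non-T base is absorbed only while the
    mismatch budget (1 per started 10 nt, counted over the run so far)
    allows it and a T follows.  Returns 0 when the run is shorter than
    ``min_t_run``.
    """
    i = 0
    mismatches = 0
    n = len(seq)
    while i < n:
        if seq[i] == "T":
            i += 1
            continue
        budget = (i // 10) + 1
        if mismatches + 1 <= budget and i + 1 < n and seq[i + 1] == "T":
            mismatches += 1
            i += 1
            continue
        break
    return i if i >= min_t_run else 0


def trim_polyT(
    read: ReadRecord,
    min_t_run: int = DEFAULT_MIN_T_RUN,
    min_length: int = MIN_POST_TRIM_LENGTH,
) -> tuple[ReadRecord, int] | None:
    """Trim the 5' oligo-dT complement; reject reads without one.

    Returns (trimmed read, t-run length), or None when the read has no
    leading poly-T run of at least ``min_t_run`` nt or the remainder is
    shorter than ``min_length``.
    """
    run = _leading_t_run(read.seq, min_t_run)
    if run == 0:
        return None
    remainder = read.seq[run:]
    if len(remainder) < min_length:
        return None
    return ReadRecord(read.id, remainder, read.qual[run:]), run


def preprocess_reads(
    reads: Iterable[ReadRecord],
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    max_homopolymer_frac: float = DEFAULT_MAX_HOMOPOLYMER_FRAC,
    min_t_run: int = DEFAULT_MIN_T_RUN,
    min_length: int = MIN_POST_TRIM_LENGTH,
) -> tuple[list[ReadRecord], list[tuple[str, str]], dict[str, int]]:
    """Full cleaning stage: quality filter -> polyNT filter -> poly-T trim.

    Returns (kept trimmed reads, [(read id, drop reason)], stage counts).
    """
    reads = list(reads)
    q_kept, q_drop = filter_quality(reads, min_mean_q, max_n_frac)
    nt_kept, nt_drop = filter_polyNT(q_kept, max_homopolymer_frac)
    kept: list[ReadRecord] = []
    audit: list[tuple[str, str]] = [(r.id, reason) for r, reason in q_drop]
    audit += [(r.id, reason) for r, reason in nt_drop]
    for r in nt_kept:
        res = trim_polyT(r, min_t_run, min_length)
        if res is None:
            audit.append((r.id, "no_polyT"))
        else:
            kept.append(res[0])
    counts = {
        "raw": len(reads),
        "quality_pass": len(q_kept),
        "polyNT_pass": len(nt_kept),
        "polyT_pass": len(kept),
    }
    return kept, audit, counts
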