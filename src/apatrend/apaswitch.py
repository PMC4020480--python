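"""Tandem 3'-UTR switch testing between two samples.

For each gene with two or more tandem polyA sites, reads are laid out in a
2 x k count table: columns are the tandem sites ordered by 3'-UTR length,
row one is sample one, row two is sample two.  Each read is an observation
(X, Y) with X the sample index (1 or 2) and Y the 3'-UTR length of its
site.  The tandem APA switch index (TSI) is the Pearson correlation r of X
and Y over the n reads, computed from count-weighted moments; the linear
trend statistic M^2 = (n - 1) r^2 is referred to the chi-square distribution
with one degree of freedom.  TSI > 0 means sample two's reads sit at longer
UTRs (lengthening in sample two); TSI < 0 means shortening.  Genes with
|r| > 0.1 and Benjamini-Hochberg FDR < 0.01 are called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .refio import TranscriptModel, gene_anchors
from .sitecall import PolyASite

R_CUT = 0.1
FDR_CUT = 0.01
MIN_READS = 30
ADMISSIBLE_REGIONS = {"UTR3", "downstream1k"}


@dataclass
class TandemTable:
    """Per-gene ordered tandem-site count table for two samples."""

    gene_id: str
    utr_lengths: tuple[int, ...]  # Y_1 < Y_2 < ... < Y_k, in nt
    counts: np.ndarray  # shape (2, k); row 0 = sample one, row 1 = sample two

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, len(self.utr_lengths)):
            raise ValueError(f"{self.gene_id}: counts shape mismatch")
        if len(self.utr_lengths) < 2:
            raise ValueError(f"{self.gene_id}: need >= 2 tandem sites")
        if any(y <= 0 for y in self.utr_lengths) or any(
            b <= a for a, b in zip(self.utr_lengths, self.utr_lengths[1:])
        ):
            raise ValueError(f"{self.gene_id}: UTR lengths must be positive, strictly increasing")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class SwitchResult:
    gene_id: str
    tsi: float = math.nan
    m2: float = math.nan
    p: float = math.nan
    fdr: float = math.nan
    call: str = "none"  # shortened | lengthened | none | excluded(<reason>)
    k: int = 0
    n: int = 0

    @property
    def excluded(self) -> bool:
        return self.call.startswith("excluded")


def utr_length(pos: int, anchor: int, strand: str) -> int:
    """Strand-aware 3'-UTR length of a cleavage position (minimum 1 nt)."""
    return pos - anchor + 1 if strand == "+" else anchor - pos


def build_tandem_table(
    gene_sites: list[PolyASite],
    anchor: int,
    strand: str,
    sample_order: tuple[str, str],
    min_reads: int = MIN_READS,
) -> TandemTable | SwitchResult:
    """Build a gene's tandem table, or a SwitchResult with an exclusion.

    Sites upstream of the anchor (non-positive UTR length) are dropped with
    a warning-free skip; exclusion reasons, in order of checking:
    ``single_site`` (< 2 usable sites), ``not_expressed_both`` (zero reads
    in a sample row), ``min_reads`` (n < ``min_reads``).
    """
    gene_id = gene_sites[0].gene_id or "?"
    usable = []
    for s in gene_sites:
        y = utr_length(s.pos, anchor, strand)
        if y > 0:
            usable.append((y, s))
    if len(usable) < 2:
        return SwitchResult(gene_id, call="excluded(single_site)")
    usable.sort(key=lambda t: t[0])
    ys = tuple(y for y, _ in usable)
    counts = np.array(
        [[s.counts.get(smp, 0) for _, s in usable] for smp in sample_order], dtype=float
    )
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        return SwitchResult(gene_id, call="excluded(not_expressed_both)")
    if counts.sum() < min_reads:
        return SwitchResult(gene_id, call="excluded(min_reads)")
    return TandemTable(gene_id, ys, counts)


def tsi(table: TandemTable) -> float:
    """Count-weighted Pearson r between sample index X and UTR length Y.

    Equals the Pearson correlation over the n expanded per-read (X, Y)
    observations, with X = 1 for sample one and X = 2 for sample two.
    Returns NaN when either marginal is degenerate (all reads in one sample
    row, or all reads at one UTR length).
    """
    c = table.counts
    n = c.sum()
    if n == 0:
        return math.nan
    x = np.array([1.0, 2.0])
    y = np.asarray(table.utr_lengths, dtype=float)
    w_x = c.sum(axis=1) / n
    w_y = c.sum(axis=0) / n
    mu_x = float(w_x @ x)
    mu_y = float(w_y @ y)
    var_x = float(w_x @ (x - mu_x) ** 2)
    var_y = float(w_y @ (y - mu_y) ** 2)
    if var_x <= 0 or var_y <= 0:
        return math.nan
    cov = float((x - mu_x) @ (c / n) @ (y - mu_y))
    return cov / math.sqrt(var_x * var_y)


def trend_test(table: TandemTable) -> SwitchResult:
    """Linear trend test on one tandem table (call made later, post-FDR)."""
    r = tsi(table)
    k, n = len(table.utr_lengths), table.n
    if math.isnan(r):
        return SwitchResult(table.gene_id, call="excluded(degenerate)", k=k, n=n)
    m2 = (n - 1) * r * r
    p = float(stats.chi2.sf(m2, df=1))
    return SwitchResult(table.gene_id, tsi=r, m2=m2, p=p, k=k, n=n)


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]  # enforce monotonicity
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_switch(
    results: list[SwitchResult],
    r_cut: float = R_CUT,
    fdr_cut: float = FDR_CUT,
) -> list[SwitchResult]:
    """BH-adjust over tested genes and call shortened/lengthened.

    shortened: r < -r_cut and FDR < fdr_cut (sample two uses shorter UTRs);
    lengthened: r > r_cut and FDR < fdr_cut; otherwise none.  Excluded
    genes pass through unchanged and do not enter the FDR adjustment.
    """
    tested = [r for r in results if not r.excluded]
    fdrs = bh_fdr([r.p for r in tested]) if tested else np.array([])
    adjusted = {}
    for res, q in zip(tested, fdrs):
        if res.tsi < -r_cut and q < fdr_cut:
            call = "shortened"
        elif res.tsi > r_cut and q < fdr_cut:
            call = "lengthened"
        else:
            call = "none"
        adjusted[id(res)] = replace(res, fdr=float(q), call=call)
    return [adjusted.get(id(r), r) for r in results]


def switch_analysis(
    sites: list[PolyASite],
    transcripts: list[TranscriptModel],
    sample_order: tuple[str, str],
    r_cut: float = R_CUT,
    fdr_cut: float = FDR_CUT,
    min_reads: int = MIN_READS,
) -> tuple[list[SwitchResult], dict[str, TandemTable]]:
    """Full stage: group admissible sites per gene, build tables, test, call."""
    anchors = gene_anchors(transcripts)
    by_gene: dict[str, list[PolyASite]] = {}
    for s in sites:
        if s.gene_id and s.region in ADMISSIBLE_REGIONS:
            by_gene.setdefault(s.gene_id, []).append(s)

    results: list[SwitchResult] = []
    tables: dict[str, TandemTable] = {}
    for gene_id in sorted(by_gene):
        if gene_id not in anchors:
            continue
        _chrom, strand, anchor, _tes = anchors[gene_id]
        built = build_tandem_table(by_gene[gene_id], anchor, strand, sample_order, min_reads)
        if isinstance(built, SwitchResult):
            results.append(built)
        else:
            tables[gene_id] = built
            results.append(trend_test(built))
    return call_switch(results, r_cut, fdr_cut), tables


def results_to_frame(
    results: list[SwitchResult], tables: dict[str, TandemTable] | None = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "k": r.k,
            "n": r.n,
            "tsi": r.tsi,
            "m2": r.m2,
            "p": r.p,
            "fdr": r.fdr,
            "call": r.call,
        }
        if tables and r.gene_id in tables:
            t = tables[r.gene_id]
            row["utr_lengths"] = ",".join(str(y) for y in t.utr_lengths)
            row["counts_s1"] = ",".join(str(int(c)) for c in t.counts[0])
            row["counts_s2"] = ",".join(str(int(c)) for c in t.counts[1])
        rows.append(row)
    return pd.DataFrame(rows)
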