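import numpy as np
import pytest

from apatrend import sitecall
from apatrend.refio import GenomeRef, KnownSiteDB, KnownSiteRecord, TranscriptModel
from apatrend.sitecall import (
    CleavageEvent,
    annotate_site,
    cluster_events,
    downstream_window,
    extract_cleavage,
    internal_priming_filter,
    is_internal_priming,
    summarize_run,
)


def ev(pos, sample="s1", strand="+", chrom="chr1"):
    return CleavageEvent(chrom, strand, pos, sample)


class TestExtractCleavage:
    def test_bed_strand_conventions(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t140\tr1\t0\t+\nchr1\t100\t140\tr2\t0\t-\n")
        events = extract_cleavage(str(bed), "s1")
        assert (events[0].pos, events[1].pos) == (139, 100)

    def test_sam_unique_only_drops_multimappers(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 1000, "SN": "chr1"}]}
        path = str(tmp_path / "a.sam")
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for name, start, nh in (("u1", 100, 1), ("u2", 200, 1), ("m1", 300, 3)):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "A" * 40
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "40M"
                a.mapping_quality = 30
                a.set_tag("NH", nh)
                fh.write(a)
        events = extract_cleavage(path, "s1", unique_only=True)
        assert len(events) == 2
        assert {e.pos for e in events} == {139, 239}

    def test_sam_unmapped_skipped(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 1000, "SN": "chr1"}]}
        path = str(tmp_path / "a.sam")
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            a = pysam.AlignedSegment()
            a.query_name = "x"
            a.query_sequence = "A" * 40
            a.is_unmapped = True
            fh.write(a)
        assert extract_cleavage(path, "s1") == []


class TestInternalPriming:
    def test_all_a_window_filtered(self):
        assert is_internal_priming("A" * 20)

    def test_mixed_window_kept(self):
        assert not is_internal_priming("ACGTACGTACGTACGTACGT")

    def test_twelve_scattered_a_filtered_eleven_kept(self):
        exact12 = "AAAACAAAACAAAACCCCCC"  # scattered runs of 4, no 8-mer, no G
        assert exact12.count("A") == 12
        assert is_internal_priming(exact12)
        eleven = "ACACACACACACACACACAA"  # 11 A, max run 2, no pattern
        assert eleven.count("A") == 11
        assert not is_internal_priming(eleven)

    def test_eight_mer_rule_fires_below_twelve_total(self):
        win = "AAAAAAAACGTCGTCGTCGT"
        assert win.count("A") == 8
        assert is_internal_priming(win)

    def test_g_a_pattern_rule(self):
        win = "GAAAAGAAAGCTCTCTCTCT"
        assert win.count("A") < 12 and "AAAAAAAA" not in win
        assert is_internal_priming(win)
        longer_runs = "GAAAAAAGAAAAGCCCCCCC"  # G A{6} G A{4} G matches A{4,}/A{3,}
        assert is_internal_priming(longer_runs)

    def test_downstream_window_strand_aware(self):
        #            0123456789
        genome = GenomeRef({"c": "CCCCCTTTTTGGGGGAAAAA"})
        plus = downstream_window(CleavageEvent("c", "+", 4, "s"), genome, window=5)
        assert plus == "TTTTT"
        minus = downstream_window(CleavageEvent("c", "-", 5, "s"), genome, window=5)
        assert minus == "GGGGG"  # revcomp of CCCCC

    def test_window_truncated_at_contig_end(self):
        genome = GenomeRef({"c": "CCCCAA"})
        win = downstream_window(CleavageEvent("c", "+", 3, "s"), genome, window=20)
        assert win == "AA"

    def test_filter_split(self):
        genome = GenomeRef({"c": "C" * 30 + "A" * 30 + "C" * 40})
        keep = CleavageEvent("c", "+", 5, "s")
        kill = CleavageEvent("c", "+", 29, "s")
        kept, filtered = internal_priming_filter([keep, kill], genome)
        assert kept == [keep] and filtered == [kill]


class TestClusterEvents:
    def test_chained_cluster_within_gap(self):
        sites = cluster_events([ev(100), ev(110), ev(130)])
        assert len(sites) == 1 and sites[0].total == 3

    def test_singletons_discarded(self):
        assert cluster_events([ev(100), ev(130)]) == []

    def test_order_invariance(self, rng):
        events = [ev(int(p), sample=f"s{p % 2}") for p in rng.integers(0, 2000, size=300)]
        a = cluster_events(events)
        perm = [events[i] for i in rng.permutation(len(events))]
        b = cluster_events(perm)
        assert [(s.chrom, s.pos, s.total) for s in a] == [(s.chrom, s.pos, s.total) for s in b]
        for s_a, s_b in zip(a, b):
            assert s_a.counts == s_b.counts

    def test_representative_is_pooled_mode_tie_three_prime(self):
        events = [ev(100), ev(100), ev(105), ev(105), ev(110)]
        (site,) = cluster_events(events)
        assert site.pos == 105  # tie between 100 and 105 -> 3'-most on +
        events_minus = [ev(100, strand="-"), ev(100, strand="-"), ev(105, strand="-"), ev(105, strand="-")]
        (site_m,) = cluster_events(events_minus)
        assert site_m.pos == 100  # 3'-most on - is the smallest coordinate

    def test_every_event_in_exactly_one_cluster_and_gap_invariant(self, rng):
        events = [ev(int(p)) for p in rng.integers(0, 5000, size=400)]
        sites = cluster_events(events, min_reads=1)
        assert sum(s.total for s in sites) == len(events)
        for s in sites:
            pos = sorted(s.positions)
            assert all(b - a <= 24 for a, b in zip(pos, pos[1:]))

    def test_sample_label_invariance(self):
        events = [ev(100, "s1"), ev(105, "s2"), ev(110, "s1")]
        swapped = [CleavageEvent(e.chrom, e.strand, e.pos, {"s1": "s2", "s2": "s1"}[e.sample_id]) for e in events]
        (a,), (b,) = cluster_events(events), cluster_events(swapped)
        assert a.counts["s1"] == b.counts["s2"] and a.counts["s2"] == b.counts["s1"]


def _tx(gene, strand, cds_end, tes, tx_start, tx_end, cds_start=None):
    return TranscriptModel(
        gene_id=gene, chrom="chr1", strand=strand, cds_end=cds_end, tes=tes,
        tx_start=tx_start, tx_end=tx_end, cds_start=cds_start,
        exons=((tx_start, tx_end),), coding=True,
    )


class TestAnnotateSite:
    transcripts = [_tx("gA", "+", 1000, 2000, 500, 2000, cds_start=600)]
    known = KnownSiteDB([KnownSiteRecord("chr1", "+", 5000, "k1")])

    def site(self, pos, strand="+"):
        from apatrend.sitecall import PolyASite

        return PolyASite("chr1", strand, pos, {"s1": 2})

    def test_near_tes_is_ucsc_utr3(self):
        s = annotate_site(self.site(1990), self.transcripts, self.known)
        assert (s.tier, s.region, s.gene_id) == ("UCSC", "UTR3", "gA")

    def test_past_tes_no_match_is_novel_downstream(self):
        s = annotate_site(self.site(2300), self.transcripts, self.known)
        assert (s.tier, s.region) == ("novel", "downstream1k")

    def test_known_db_match_is_tiandb(self):
        s = annotate_site(self.site(5010), self.transcripts, self.known)
        assert s.tier == "TianDB"

    def test_tier_priority_ucsc_over_tiandb(self):
        known = KnownSiteDB([KnownSiteRecord("chr1", "+", 1995, "k")])
        s = annotate_site(self.site(1995), self.transcripts, known)
        assert s.tier == "UCSC"

    def test_cds_and_intergenic_regions(self):
        assert annotate_site(self.site(700), self.transcripts, self.known).region == "CDS"
        assert annotate_site(self.site(4000), self.transcripts, self.known).region == "intergenic"

    def test_strand_mismatch_ignored(self):
        s = annotate_site(self.site(1990, strand="-"), self.transcripts, self.known)
        assert s.tier == "novel"

    def test_equidistant_tie_goes_to_five_prime_gene(self):
        # pos 1024 is 24 nt from both annotated ends (1000 and 1048)
        txs = [
            _tx("gLeft", "+", 900, 1000, 500, 1000, cds_start=600),
            _tx("gRight", "+", 1040, 1048, 1020, 1048, cds_start=1030),
        ]
        s = annotate_site(self.site(1024), txs, KnownSiteDB([]))
        assert abs(1024 - 1000) == abs(1024 - 1048) == 24
        assert s.gene_id == "gLeft"


class TestSummarizeRun:
    def test_percentages_of_raw_to_one_decimal(self):
        df = summarize_run({"normal": {"raw": 23_059_686, "clean": 21_807_523}})
        row = df[df.stage == "Clean reads"].iloc[0]
        assert row.pct_of_raw == 94.6

    def test_equal_counts_give_hundred(self):
        df = summarize_run({"s": {"raw": 5, "clean": 5}})
        assert df[df.stage == "Clean reads"].iloc[0].pct_of_raw == 100.0

    def test_monotonicity_violation_rejected(self):
        with pytest.raises(ValueError):
            summarize_run({"s": {"raw": 10, "clean": 11}})
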