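import numpy as np
import pytest
from scipy import stats

from apatrend import sitecall
from apatrend.sitecall import downstream_window, is_internal_priming, CleavageEvent
from apatrend.simdata import (
    SimConfig,
    make_reference,
    score_recovery,
    simulate_reads,
    simulate_tandem_tables,
    truth_frame,
    write_dataset,
)


class TestMakeReference:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimConfig(n_genes=10, depth=1000, seed=5)
        a, b = make_reference(cfg), make_reference(cfg)
        assert a.genome.sequences == b.genome.sequences
        assert truth_frame(a.truth).equals(truth_frame(b.truth))
        c = make_reference(SimConfig(n_genes=10, depth=1000, seed=6))
        assert a.genome.sequences != c.genome.sequences

    def test_site_spacing_at_least_sixty(self, reference):
        for gt in reference.truth.genes.values():
            pos = sorted(gt.site_positions)
            assert all(b - a >= 60 for a, b in zip(pos, pos[1:]))

    def test_known_site_fraction_exact(self, reference, sim_config):
        candidates = sum(len(g.site_positions) - 1 for g in reference.truth.genes.values())
        expected = int(round(sim_config.known_site_frac * candidates))
        assert len(reference.known_db) == expected

    def test_true_site_windows_are_clean(self, reference):
        """Downstream windows of every planted site (and every jittered
        position around it) carry <8 consecutive A, <12 total A and no
        G/A disruption pattern, so true reads survive the filter."""
        from apatrend.simdata import JITTER_TRUNC

        for gt in reference.truth.genes.values():
            for p in gt.site_positions:
                for dj in (-JITTER_TRUNC, 0, JITTER_TRUNC):
                    ev = CleavageEvent(gt.chrom, gt.strand, p + dj, "s")
                    win = downstream_window(ev, reference.genome)
                    assert not is_internal_priming(win), (gt.gene_id, p, dj, win)

    def test_decoy_windows_are_all_a(self, reference):
        for chrom, strand, pos in reference.truth.decoy_positions:
            ev = CleavageEvent(chrom, strand, pos, "s")
            assert downstream_window(ev, reference.genome) == "A" * 20

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            make_reference(SimConfig(n_genes=10, sites_per_gene=(1, 1)))

    def test_gene_sets_cover_planted_labels(self, reference):
        short = {g for g, t in reference.truth.genes.items() if t.switch_label == "shortened"}
        assert short <= reference.gene_sets.members("SET_SHORT")


class TestSimulateReads:
    def test_jitter_zero_reads_sit_on_true_sites(self):
        cfg = SimConfig(n_genes=15, depth=2000, seed=3, jitter_sd=0.0, decoy_rate=0.0)
        ref = make_reference(cfg)
        sim = simulate_reads(ref, cfg)
        true_pos = {
            (g.chrom, g.strand, p) for g in ref.truth.genes.values() for p in g.site_positions
        }
        for e in sim.events1 + sim.events2:
            assert (e.chrom, e.strand, e.pos) in true_pos

    def test_realized_counts_within_multinomial_ci(self, reference, sim_reads, sim_config):
        """Per-site realized counts agree with expected usage proportions:
        for the most expressed gene, each site count stays inside the
        99.9% binomial envelope of its planted usage."""
        genes = reference.truth.genes
        g = max(genes, key=lambda g: sum(genes[g].counts1))
        gt = genes[g]
        n = sum(gt.counts1)
        for c, u in zip(gt.counts1, gt.usage1):
            lo, hi = stats.binom.ppf([0.0005, 0.9995], n, u)
            assert lo <= c <= hi

    def test_decoy_reads_fail_internal_priming_filter(self, reference, sim_reads):
        decoys = {(c, s, p) for c, s, p in reference.truth.decoy_positions}
        events = sim_reads.events1 + sim_reads.events2
        kept, filtered = sitecall.internal_priming_filter(events, reference.genome)
        assert all((e.chrom, e.strand, e.pos) not in decoys for e in kept)
        n_decoy_events = sum(1 for e in events if (e.chrom, e.strand, e.pos) in decoys)
        assert n_decoy_events > 0 and len(filtered) >= n_decoy_events

    def test_fastq_reads_start_with_poly_t_and_match_genome(self, reference, sim_reads):
        from apatrend.sitecall import revcomp

        genome = reference.genome
        for read, event in zip(sim_reads.reads1[:50], sim_reads.events1[:50]):
            assert _leading_t(read.seq) >= 8
            if event.strand == "+":
                body = revcomp(genome.fetch(event.chrom, event.pos - 49, event.pos + 1))
            else:
                body = genome.fetch(event.chrom, event.pos, event.pos + 50)
            assert read.seq.endswith(body)

    def test_byte_identical_outputs_across_reruns(self, tmp_path):
        cfg = SimConfig(n_genes=8, depth=800, seed=11)
        files = []
        for sub in ("a", "b"):
            ref = make_reference(cfg)
            sim = simulate_reads(ref, cfg)
            paths = write_dataset(ref, sim, tmp_path / sub)
            files.append(paths)
        for key in files[0]:
            a = open(files[0][key], "rb").read()
            b = open(files[1][key], "rb").read()
            assert a == b, f"{key} differs between reruns"


def _leading_t(seq: str) -> int:
    i = 0
    while i < len(seq) and seq[i] == "T":
        i += 1
    return i


class TestSimulateTandemTables:
    def test_shapes_and_totals(self, rng):
        tables = simulate_tandem_tables(5, 100, (0.5, 0.5), None, (100, 400), rng)
        assert len(tables) == 5
        for t in tables:
            assert t.n == 200 and t.counts.shape == (2, 2)

    def test_null_tables_share_usage(self, rng):
        tables = simulate_tandem_tables(200, 500, (0.7, 0.3), None, (100, 400), rng)
        prox1 = np.mean([t.counts[0, 0] / t.counts[0].sum() for t in tables])
        prox2 = np.mean([t.counts[1, 0] / t.counts[1].sum() for t in tables])
        assert prox1 == pytest.approx(0.7, abs=0.02)
        assert prox2 == pytest.approx(0.7, abs=0.02)


class TestScoreRecovery:
    def test_truth_vs_truth_perfect(self, reference):
        from apatrend.apaswitch import SwitchResult
        from apatrend.expression import DEGResult
        from apatrend.sitecall import PolyASite

        sites = [
            PolyASite(g.chrom, g.strand, p, {"s1": 5})
            for g in reference.truth.genes.values()
            for p in g.site_positions
        ]
        sw = [
            SwitchResult(g, tsi=0.5, p=0.001, fdr=0.001,
                         call=t.switch_label if t.switch_label != "null" else "none")
            for g, t in reference.truth.genes.items()
        ]
        deg = [
            DEGResult(g, 1, 1, 0.0, 1.0, 1.0, t.deg_label if t.deg_label != "null" else "none")
            for g, t in reference.truth.genes.items()
        ]
        rep = score_recovery(sites, sw, deg, reference.truth)
        assert rep["site_sensitivity"] == 1.0
        assert rep["site_positional_error_mean"] == 0.0
        assert rep["switch_empirical_fdr"] == 0.0

    def test_unknown_gene_rejected(self, reference):
        from apatrend.apaswitch import SwitchResult

        with pytest.raises(ValueError, match="unknown gene"):
            score_recovery([], [SwitchResult("nope")], [], reference.truth)
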