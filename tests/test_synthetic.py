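"""Generator determinism, planted-structure correctness, ledger completeness."""

import pytest

from cneduo import io_formats as iof
from cneduo.complementarity import complementarity_profile, revcomp
from cneduo.io_formats import GenomicInterval
from cneduo.synthetic import (
    SimulationConfig,
    simulate_ancestral_cluster,
    simulate_cage_and_signals,
    simulate_expression_matrix,
    simulate_intron_retained_reads,
    simulate_wgd_and_divergence,
)

ELEMENT = GenomicInterval("chr1", 7000, 7032)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(cne_length=0)
        with pytest.raises(ValueError):
            SimulationConfig(retention_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(couplings={"g": 1.5})


class TestAncestor:
    def test_planted_element_width_and_position(self):
        cfg = SimulationConfig(seed=1, cne_length=32)
        anc = simulate_ancestral_cluster(cfg)
        iv = anc.cne_interval
        assert iv.width == 32
        genes = {t.gene_id: t.interval for t in anc.transcripts}
        assert genes["gene11"].end <= iv.start and iv.end <= genes["gene12"].start
        # plus strand carries the reverse complement of the host-oriented element
        assert anc.genome["anc"][iv.start : iv.end] == revcomp(anc.cne_seq)

    def test_determinism_same_seed(self):
        a = simulate_ancestral_cluster(SimulationConfig(seed=7))
        b = simulate_ancestral_cluster(SimulationConfig(seed=7))
        assert a.genome == b.genome and a.cne_seq == b.cne_seq

    def test_different_seed_differs(self):
        a = simulate_ancestral_cluster(SimulationConfig(seed=7))
        b = simulate_ancestral_cluster(SimulationConfig(seed=8))
        assert a.genome != b.genome


class TestClade:
    def test_zero_rate_preserves_ancestral_copy_and_complementarity(self):
        cfg = SimulationConfig(seed=2, substitution_rate=0.0)
        anc = simulate_ancestral_cluster(cfg)
        clade = simulate_wgd_and_divergence(anc, cfg)
        for sp, pair in clade.pairs.items():
            assert pair.seq_c == anc.cne_seq
            assert complementarity_profile(pair).score == 1.0

    def test_every_species_has_both_clusters(self):
        cfg = SimulationConfig(seed=2)
        clade = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        for sp in clade.genomes:
            assert (sp, "C") in clade.ledger.cne_intervals
            assert (sp, "D") in clade.ledger.cne_intervals

    def test_d_copy_planted_downstream_of_host_tss(self):
        """Minus-strand host: element start sits 55 nt downstream of the TSS."""
        cfg = SimulationConfig(seed=2)
        clade = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        for sp in clade.genomes:
            host = next(t for t in clade.annotations[sp] if t.gene_id.startswith("hostD"))
            iv = clade.ledger.cne_intervals[(sp, "D")]
            assert host.interval.end - iv.end == 55

    def test_event_count_exceeding_columns_is_error(self):
        cfg = SimulationConfig(seed=2, cne_length=8, n_compensatory_events=5)
        anc = simulate_ancestral_cluster(cfg)
        with pytest.raises(ValueError, match="exceed"):
            simulate_wgd_and_divergence(anc, cfg)

    def test_ledger_completeness(self):
        """Every planted item appears exactly once in the ledger frame."""
        cfg = SimulationConfig(seed=3, n_compensatory_events=3, drop_c_in=("gar",))
        clade = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        frame = clade.ledger.to_frame()
        events = frame[frame.section == "compensatory_event"]
        assert len(events) == 3
        intervals = frame[frame.section == "cne_interval"]
        expected = 2 * len(clade.genomes) - 1  # gar lost its C copy
        assert len(intervals) == expected
        assert not frame.duplicated().any()

    def test_genome_bytes_deterministic(self):
        cfg = SimulationConfig(seed=4, n_compensatory_events=2)
        a = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        b = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        assert a.genomes == b.genomes and a.ledger.events == b.ledger.events


class TestGeneratedFilesParse:
    def test_round_trip_through_io_formats(self, tmp_path):
        cfg = SimulationConfig(seed=5, read_depth=200, n_samples=20)
        anc = simulate_ancestral_cluster(cfg)
        clade = simulate_wgd_and_divergence(anc, cfg)
        sp = next(iter(clade.genomes))
        iof.write_fasta(clade.genomes[sp], tmp_path / "g.fa")
        assert iof.read_fasta(tmp_path / "g.fa") == clade.genomes[sp]
        iof.write_gff3(clade.annotations[sp], tmp_path / "g.gff3")
        parsed = iof.read_gff3(tmp_path / "g.gff3")
        assert sorted(t.transcript_id for t in parsed) == sorted(
            t.transcript_id for t in clade.annotations[sp]
        )
        host = next(t for t in clade.annotations[sp] if t.gene_id.startswith("hostC"))
        libs = simulate_intron_retained_reads(host, cfg)
        iof.write_bed12(libs["nuclear"], tmp_path / "r.bed12")
        assert iof.read_bed12(tmp_path / "r.bed12") == libs["nuclear"]
        sc = simulate_cage_and_signals(ELEMENT, "active", cfg)
        iof.write_ctss_bed(sc.ctss, tmp_path / "c.bed")
        assert iof.read_ctss_bed(tmp_path / "c.bed") == sc.ctss
        iof.write_bedgraph(sc.tracks["dhs"], tmp_path / "d.bedgraph")
        back = iof.read_bedgraph(tmp_path / "d.bedgraph")
        assert back.seq_id == sc.tracks["dhs"].seq_id
        assert len(back.values) == len(sc.tracks["dhs"].values)
        matrix, _ = simulate_expression_matrix(cfg)
        iof.write_expression_tsv(matrix, tmp_path / "e.tsv")
        assert iof.read_expression_tsv(tmp_path / "e.tsv") == matrix


class TestCageScenarios:
    def test_closed_has_no_ctss_and_baseline_signals(self):
        cfg = SimulationConfig(seed=6)
        sc = simulate_cage_and_signals(ELEMENT, "closed", cfg)
        assert sc.ctss == []
        core, _ = sc.tracks["dhs"].mean(ELEMENT.start, ELEMENT.end)
        assert core == pytest.approx(0.1, abs=0.01)

    def test_active_dominant_spacing_matches_config(self):
        cfg = SimulationConfig(seed=6, cage_spacing=180)
        sc = simulate_cage_and_signals(ELEMENT, "active", cfg)
        minus = max((r for r in sc.ctss if r.position.strand == "-"), key=lambda r: r.tag_count)
        plus = max((r for r in sc.ctss if r.position.strand == "+"), key=lambda r: r.tag_count)
        assert plus.position.start - minus.position.start == 180

    def test_promoter_ctss_tied_to_coupling(self):
        cfg = SimulationConfig(seed=6, cage_tag_count=30)
        sc = simulate_cage_and_signals(ELEMENT, "active", cfg,
                                       promoter_position=5000, promoter_coupling=0.5)
        (rec,) = sc.promoter_ctss
        assert rec.tag_count == 15

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=6, signal_noise=0.2)
        a = simulate_cage_and_signals(ELEMENT, "active", cfg)
        b = simulate_cage_and_signals(ELEMENT, "active", cfg)
        assert a.ctss == b.ctss
        assert a.tracks["dhs"].values == b.tracks["dhs"].values


class TestExpression:
    def test_coupling_magnitude_bound_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(couplings={"g": -1.2})

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_expression_matrix(SimulationConfig(seed=1, n_samples=5))

    def test_zeroed_fraction_applied(self):
        cfg = SimulationConfig(seed=7, n_samples=100, zero_fraction=0.3)
        m, ledger = simulate_expression_matrix(cfg)
        zeros = (m.feature("CNE") == 0).sum()
        assert zeros == 30 and len(ledger.zeroed_samples) == 30
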