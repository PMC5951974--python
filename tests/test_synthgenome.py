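"""Generator contracts: reference invariants, event planting, reads, contigs."""

import numpy as np
import pytest

from gutstab import effects
from gutstab import synthgenome as sg
from gutstab.seqs import gc_fraction, hamming, revcomp

from conftest import micro_config


class TestBuildReference:
    def test_desk_default_structure(self, desk_ref):
        ref = desk_ref
        assert len(ref.replicons) == 8
        assert sum(r.role == sg.CHROMOSOME for r in ref.replicons) == 1
        assert len(ref.rrna_copies) == 5
        for _, s, e, _ in ref.rrna_copies:
            assert e - s + 1 == 2923

    def test_rrna_pairwise_identity_above_999(self, desk_ref):
        seqs = []
        for rid, s, e, strand in desk_ref.rrna_copies:
            x = desk_ref.replicon(rid).sequence[s - 1 : e]
            seqs.append(x if strand == "+" else revcomp(x))
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                assert hamming(a, b) <= 2
                assert 1 - hamming(a, b) / len(a) > 0.999

    def test_gc_within_one_percent(self, desk_ref):
        full = "".join(r.sequence for r in desk_ref.replicons)
        assert abs(gc_fraction(full) - 0.445) <= 0.01

    def test_intervals_within_bounds_and_cds_frame(self, desk_ref):
        lengths = {r.id: r.length for r in desk_ref.replicons}
        for g in desk_ref.gene_models:
            assert 1 <= g.start <= g.end <= lengths[g.replicon_id]
            assert g.length % 3 == 0
        for rid, s, e in desk_ref.repeat_regions:
            assert 1 <= s <= e <= lengths[rid]

    def test_cds_translates_without_internal_stop(self, desk_ref):
        for g in desk_ref.gene_models[:40]:
            seq = desk_ref.replicon(g.replicon_id).sequence[g.start - 1 : g.end]
            cds = seq if g.strand == "+" else revcomp(seq)
            aas = [effects.translate_codon(cds[i : i + 3])
                   for i in range(0, len(cds) - 3, 3)]
            assert "X" not in aas
            assert effects.translate_codon(cds[-3:]) == "X"

    def test_homology_map_segments_align_at_90(self, desk_ref):
        chrom = desk_ref.chromosome.sequence
        for h in desk_ref.homology_map:
            pseg = desk_ref.replicon(h.plasmid_id).sequence[
                h.plasmid_start - 1 : h.plasmid_end]
            cseg = chrom[h.chrom_start - 1 : h.chrom_end]
            ident = 1 - hamming(pseg, cseg) / len(pseg)
            assert ident >= 0.90

    def test_deterministic_for_fixed_seed(self):
        a = sg.build_reference(micro_config(), seed=99)
        b = sg.build_reference(micro_config(), seed=99)
        assert a.sequences() == b.sequences()
        c = sg.build_reference(micro_config(), seed=100)
        assert c.sequences() != a.sequences()

    def test_rejects_extreme_gc(self):
        cfg = micro_config()
        cfg.gc = 0.1
        with pytest.raises(ValueError, match="GC"):
            sg.build_reference(cfg, seed=1)

    def test_rejects_plasmid_longer_than_chromosome(self):
        cfg = micro_config()
        cfg.plasmids[0].length = cfg.chrom_length + 1
        with pytest.raises(ValueError, match="shorter"):
            sg.build_reference(cfg, seed=1)

    def test_full_homologous_fraction_covers_plasmid(self):
        cfg = micro_config()
        cfg.plasmids[1].hom_fraction = 1.0
        ref = sg.build_reference(cfg, seed=3)
        (h,) = [h for h in ref.homology_map if h.plasmid_id == "p2"]
        assert (h.plasmid_start, h.plasmid_end) == (1, ref.replicon("p2").length)

    def test_save_load_roundtrip(self, micro_ref, tmp_path):
        micro_ref.save(tmp_path / "ref")
        back = sg.ReferenceGenome.load(tmp_path / "ref")
        assert back.sequences() == micro_ref.sequences()
        assert back.rrna_copies == micro_ref.rrna_copies
        assert len(back.gene_models) == len(micro_ref.gene_models)


class TestPlantEvents:
    def test_no_events_is_identity(self, micro_ref):
        strain = sg.plant_events(micro_ref, sg.EventSpec("S"), seed=1)
        assert strain.replicons == micro_ref.sequences()

    def test_complete_loss_removes_replicon(self, micro_ref):
        spec = sg.EventSpec("S", plasmid_losses=[sg.PlasmidLossSpec("p4", "complete")])
        strain = sg.plant_events(micro_ref, spec, seed=1)
        assert "p4" not in strain.replicons
        assert len(strain.replicons) == len(micro_ref.replicons) - 1
        (loss,) = strain.truth.plasmid_losses
        assert loss.true_plr == 1.0

    def test_catalog_mix_realizes_intended_classes(self, desk_ref):
        specs = sg.plan_catalog_snps(desk_ref, seed=7)
        from collections import Counter

        counts = Counter(s.effect for s in specs)
        assert counts == {effects.SYNONYMOUS: 7, effects.NON_SYNONYMOUS: 9,
                          effects.NONSENSE: 2, effects.INTERGENIC: 1}
        strain = sg.plant_events(desk_ref, sg.EventSpec("S", snps=specs), seed=1)
        assert len(strain.truth.snps) == 19
        # each substitution really landed
        for s in specs:
            assert strain.replicons[s.replicon][s.pos - 1] == s.alt
            assert desk_ref.replicon(s.replicon).sequence[s.pos - 1] == s.ref

    def test_length_conservation(self, micro_ref):
        spec = sg.EventSpec(
            "S",
            plasmid_losses=[sg.PlasmidLossSpec("p1", "partial", plr=0.5)],
            acquisitions=[sg.AcquisitionSpec(region=(50, 350))])
        strain = sg.plant_events(micro_ref, spec, seed=5)
        deleted = sum(e - s + 1 for loss in strain.truth.plasmid_losses
                      for s, e in loss.deleted_intervals)
        inserted = sum(a.length for a in strain.truth.acquisitions)
        ref_total = sum(r.length for r in micro_ref.replicons)
        derived_total = sum(len(s) for s in strain.replicons.values())
        assert derived_total == ref_total - deleted + inserted

    def test_rejects_ref_base_mismatch(self, micro_ref):
        pos = 10
        actual = micro_ref.chromosome.sequence[pos - 1]
        wrong = "A" if actual != "A" else "C"
        spec = sg.EventSpec("S", snps=[sg.SnpSpec("chr", pos, wrong, "G", "")])
        with pytest.raises(ValueError, match="mismatch"):
            sg.plant_events(micro_ref, spec, seed=1)

    def test_rejects_impossible_effect_class(self, micro_ref):
        # an intergenic position can never realize a nonsense class
        gene_ivs = [(g.start, g.end) for g in micro_ref.genes_on("chr")]
        pos = next(p for p in range(1, 2000)
                   if not any(s <= p <= e for s, e in gene_ivs))
        ref_base = micro_ref.chromosome.sequence[pos - 1]
        alt = "A" if ref_base != "A" else "C"
        spec = sg.EventSpec("S", snps=[
            sg.SnpSpec("chr", pos, ref_base, alt, effects.NONSENSE)])
        with pytest.raises(ValueError, match="impossible"):
            sg.plant_events(micro_ref, spec, seed=1)

    def test_acquisition_identity_near_90(self, micro_ref):
        spec = sg.EventSpec("S", acquisitions=[sg.AcquisitionSpec(region=(50, 350))])
        strain = sg.plant_events(micro_ref, spec, seed=2)
        (acq,) = strain.truth.acquisitions
        rid, s, e = acq.ref_homolog
        src = micro_ref.replicon(rid).sequence[s - 1 : e]
        if micro_ref.rrna_copies[0][3] == "-":
            src = revcomp(src)
        ident = 1 - hamming(acq.fragment, src) / len(src)
        assert 0.87 <= ident <= 0.92
        donor_ident = 1 - hamming(acq.fragment, acq.donor_gene) / acq.length
        assert 0.95 <= donor_ident <= 0.99


class TestSimulateReads:
    def test_pair_count_matches_depth_arithmetic(self, rng):
        from gutstab.seqs import random_dna

        genome = {"chr": random_dna(rng, 100_000, 0.445)}
        pairs = sg.simulate_reads(genome, sg.ReadSimParams(depth=100, seed=1))
        expected = 100 * 100_000 / (2 * 101)
        assert abs(len(pairs) - expected) / expected < 0.05

    def test_zero_depth_rejected(self, micro_ref):
        with pytest.raises(ValueError, match="depth"):
            sg.simulate_reads(micro_ref.sequences(), sg.ReadSimParams(depth=0))

    def test_genome_shorter_than_insert_rejected(self):
        with pytest.raises(ValueError, match="insert"):
            sg.simulate_reads({"x": "ACGT" * 50}, sg.ReadSimParams(seed=1))

    def test_error_free_reads_match_genome(self, micro_ref):
        seqs = micro_ref.sequences()
        pairs = sg.simulate_reads(seqs, sg.ReadSimParams(depth=2, seed=3))
        blob = " ".join(seqs.values())
        for rp in pairs[:200]:
            assert rp.seq1 in blob or revcomp(rp.seq1) in blob
            assert rp.seq2 in blob or revcomp(rp.seq2) in blob

    def test_deterministic_fastq(self, micro_ref, tmp_path):
        seqs = micro_ref.sequences()
        p1a, _ = sg.write_fastq_pair(
            sg.simulate_reads(seqs, sg.ReadSimParams(depth=2, seed=9)),
            tmp_path / "a")
        p1b, _ = sg.write_fastq_pair(
            sg.simulate_reads(seqs, sg.ReadSimParams(depth=2, seed=9)),
            tmp_path / "b")
        assert p1a.read_bytes() == p1b.read_bytes()

    def test_error_rate_downgrades_quality(self, micro_ref):
        pairs = sg.simulate_reads(micro_ref.sequences(),
                                  sg.ReadSimParams(depth=1, error_rate=0.05, seed=4))
        quals = "".join(rp.qual1 for rp in pairs[:500])
        frac_low = quals.count("+") / len(quals)
        assert 0.03 < frac_low < 0.07


class TestShearContigs:
    def test_single_contig_reconstructs_replicon(self, micro_ref):
        contigs = sg.shear_contigs(micro_ref.sequences(), mean_length=10**7,
                                   seed=1)
        by_rep = {c.source_replicon: c.sequence for c in contigs}
        assert by_rep == micro_ref.sequences()

    def test_contigs_partition_genome_exactly(self, micro_ref):
        contigs = sg.shear_contigs(micro_ref.sequences(), mean_length=5_000,
                                   seed=2)
        for rid, seq in micro_ref.sequences().items():
            parts = sorted((c for c in contigs if c.source_replicon == rid),
                           key=lambda c: c.source_start)
            assert "".join(p.sequence for p in parts) == seq

    def test_gap_bookkeeping(self, micro_ref):
        gap = 500
        contigs = sg.shear_contigs(micro_ref.sequences(), mean_length=5_000,
                                   gap=gap, seed=3)
        total = sum(len(c.sequence) for c in contigs)
        genome = sum(r.length for r in micro_ref.replicons)
        n_junctions = len(contigs) - len(micro_ref.replicons)
        assert genome - n_junctions * gap <= total <= genome

    def test_forced_breakpoints_respected(self, micro_ref):
        forced = {"chr": [5_000]}
        contigs = sg.shear_contigs(micro_ref.sequences(), mean_length=10**7,
                                   seed=4, forced_breakpoints=forced)
        starts = {c.source_start for c in contigs if c.source_replicon == "chr"}
        assert 5_001 in starts
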