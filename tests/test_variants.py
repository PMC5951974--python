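"""Variant calling, filtering, repeat masking, effect annotation, catalog."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutstab import effects
from gutstab import synthgenome as sg
from gutstab import variants as va
from gutstab.homology import DepthTrack
from gutstab.seqs import random_dna, revcomp

from conftest import micro_config


def make_cds_reference(codon_overrides: dict[int, str], n_codons: int = 900,
                       strand: str = "+", gene_start: int = 101,
                       seed: int = 5) -> sg.ReferenceGenome:
    """One-gene chromosome with chosen codons planted at 1-based indices."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    pool = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")]
    for i in range(2, n_codons):
        codons.append(pool[rng.integers(len(pool))])
    codons.append("TAA")
    for idx, codon in codon_overrides.items():
        codons[idx - 1] = codon
    cds = "".join(codons)
    flank5 = random_dna(rng, gene_start - 1, 0.445)
    flank3 = random_dna(rng, 200, 0.445)
    placed = cds if strand == "+" else revcomp(cds)
    chrom = flank5 + placed + flank3
    gene = sg.GeneModel("g1", "chr", gene_start, gene_start + len(cds) - 1, strand)
    return sg.ReferenceGenome(
        [sg.Replicon("chr", sg.CHROMOSOME, chrom)], [gene], [], [], [])


def plus_strand_pos(ref: sg.ReferenceGenome, codon_idx: int, offset: int) -> int:
    g = ref.gene_models[0]
    return g.start + 3 * (codon_idx - 1) + offset


class TestAnnotateEffect:
    @pytest.mark.parametrize(
        "codon_idx,codon,offset,alt,expected_type,expected_change",
        [
            # C->T at codon position 1 of CGT, codon 61: Arg -> Cys
            (61, "CGT", 0, "T", effects.NON_SYNONYMOUS, "R61C"),
            # C->T turning CAA (codon 808) into TAA: premature stop
            (808, "CAA", 0, "T", effects.NONSENSE, "Q808X"),
            # G->T at codon position 3 of GTG (codon 474): Val -> Val
            (474, "GTG", 2, "T", effects.SYNONYMOUS, "V474V"),
        ])
    def test_worked_codon_examples(self, codon_idx, codon, offset, alt,
                                   expected_type, expected_change):
        ref = make_cds_reference({codon_idx: codon})
        pos = plus_strand_pos(ref, codon_idx, offset)
        cand = va.SnpCandidate("chr", pos, codon[offset], alt)
        rec = va.annotate_effect(cand, ref)
        assert rec.mut_type == expected_type
        assert rec.protein_change == expected_change

    def test_minus_strand_codon(self):
        # gene on '-': reference-strand alleles are complemented before
        # codon lookup; CGT codon 10 with C->T is still R10C
        ref = make_cds_reference({10: "CGT"}, n_codons=50, strand="-")
        g = ref.gene_models[0]
        # codon 10 position 1 on the coding strand maps to reference
        # position end - (3*9)
        pos = g.end - 3 * 9
        cand = va.SnpCandidate("chr", pos, "G", "A")  # revcomp of C->T
        rec = va.annotate_effect(cand, ref)
        assert rec.mut_type == effects.NON_SYNONYMOUS
        assert rec.protein_change == "R10C"

    def test_intergenic_between_genes(self):
        ref = make_cds_reference({}, n_codons=50)
        cand = va.SnpCandidate("chr", 10, ref.chromosome.sequence[9], "A")
        if cand.ref == "A":
            cand.alt = "C"
        rec = va.annotate_effect(cand, ref)
        assert rec.mut_type == effects.INTERGENIC
        assert rec.protein_change == ""
        assert rec.gene_id == ""

    def test_position_beyond_replicon_rejected(self):
        ref = make_cds_reference({}, n_codons=50)
        with pytest.raises(ValueError, match="beyond"):
            va.annotate_effect(va.SnpCandidate("chr", 10**7, "A", "C"), ref)

    def test_cds_not_multiple_of_three_rejected(self):
        ref = make_cds_reference({}, n_codons=50)
        ref.gene_models[0].end += 1
        pos = plus_strand_pos(ref, 5, 0)
        base = ref.chromosome.sequence[pos - 1]
        alt = "A" if base != "A" else "C"
        with pytest.raises(ValueError, match="multiple of 3"):
            va.annotate_effect(va.SnpCandidate("chr", pos, base, alt), ref)

    def test_class_matches_whole_protein_diff_oracle(self, desk_ref):
        """Brute-force oracle: translate the whole mutated gene and diff."""
        specs = sg.plan_catalog_snps(desk_ref, seed=11)
        for spec in specs:
            rec = va.annotate_effect(
                va.SnpCandidate(spec.replicon, spec.pos, spec.ref, spec.alt),
                desk_ref)
            gene = next((g for g in desk_ref.gene_models
                         if g.replicon_id == spec.replicon
                         and g.start <= spec.pos <= g.end), None)
            if gene is None:
                assert rec.mut_type == effects.INTERGENIC
                continue
            chrom = desk_ref.chromosome.sequence
            mutated = chrom[: spec.pos - 1] + spec.alt + chrom[spec.pos :]
            def protein(seq):
                cds = seq[gene.start - 1 : gene.end]
                if gene.strand == "-":
                    cds = revcomp(cds)
                return "".join(effects.translate_codon(cds[i : i + 3])
                               for i in range(0, len(cds), 3))
            p_ref, p_mut = protein(chrom), protein(mutated)
            diffs = [(i, a, b) for i, (a, b) in enumerate(zip(p_ref, p_mut))
                     if a != b]
            if not diffs:
                oracle = effects.SYNONYMOUS
            elif diffs[0][2] == "X" and diffs[0][1] != "X":
                oracle = effects.NONSENSE
            else:
                oracle = effects.NON_SYNONYMOUS
            assert rec.mut_type == oracle == spec.effect


class TestRawCalling:
    def test_identical_contig_yields_no_candidates(self, micro_ref):
        seqs = micro_ref.sequences()
        contig = seqs["chr"][1_000:9_000]
        assert va.call_raw_snps([("c1", contig)], seqs) == []

    def test_single_planted_substitution_found(self, micro_ref):
        seqs = micro_ref.sequences()
        pos0 = 5_000
        ref_base = seqs["chr"][pos0]
        alt = "A" if ref_base != "A" else "C"
        contig = seqs["chr"][1_000:pos0] + alt + seqs["chr"][pos0 + 1 : 9_000]
        cands = va.call_raw_snps([("c1", contig)], seqs)
        assert [(c.replicon, c.pos, c.ref, c.alt) for c in cands] == \
               [("chr", pos0 + 1, ref_base, alt)]

    def test_duplicate_coverage_deduplicated(self, rng):
        # repeat-free reference so the only candidate is the planted one
        seqs = {"chr": random_dna(rng, 20_000, 0.445)}
        pos0 = 5_000
        ref_base = seqs["chr"][pos0]
        alt = "A" if ref_base != "A" else "C"
        mutated = seqs["chr"][:pos0] + alt + seqs["chr"][pos0 + 1 :]
        contigs = [("c1", mutated[1_000:9_000]), ("c2", mutated[4_000:9_500])]
        cands = va.call_raw_snps(contigs, seqs)
        assert len(cands) == 1


class TestRepeatMask:
    def test_rrna_copies_masked(self, micro_ref):
        mask = va.build_repeat_mask(micro_ref)
        for rid, s, e, _ in micro_ref.rrna_copies:
            mid = (s + e) // 2
            assert mask.contains(rid, mid)

    def test_random_sequence_unmasked(self, rng):
        seqs = {"chr": random_dna(rng, 50_000, 0.445)}
        mask = va.build_repeat_mask(seqs)
        assert mask.total_masked() == 0

    def test_exact_duplicates_both_masked(self, rng):
        seg = random_dna(rng, 200, 0.445)
        chrom = (random_dna(rng, 3_000, 0.445) + seg
                 + random_dna(rng, 3_000, 0.445) + seg
                 + random_dna(rng, 3_000, 0.445))
        mask = va.build_repeat_mask({"chr": chrom})
        assert mask.contains("chr", 3_001 + 100)
        assert mask.contains("chr", 6_201 + 100)


def _track(length: int, depth: int, alt: str, alt_count: int, pos: int):
    t = DepthTrack("chr", np.zeros(length, np.int32),
                   np.zeros((4, length), np.uint32))
    t.depth[:] = depth
    t.base_counts["ACGT".index(alt), pos - 1] = alt_count
    return t


class TestFilterSnps:
    def test_depth_exactly_ten_rejected(self):
        cand = va.SnpCandidate("chr", 50, "A", "G")
        track = _track(100, 10, "G", 10, 50)
        assert va.filter_snps([cand], {"chr": track}, va.RepeatMask()) == []

    def test_depth_eleven_full_support_retained(self):
        cand = va.SnpCandidate("chr", 50, "A", "G")
        track = _track(100, 11, "G", 11, 50)
        recs = va.filter_snps([cand], {"chr": track}, va.RepeatMask())
        assert len(recs) == 1
        assert recs[0].quality > 20

    def test_repeat_masked_position_rejected(self):
        cand = va.SnpCandidate("chr", 50, "A", "G")
        track = _track(100, 50, "G", 50, 50)
        mask = va.RepeatMask({"chr": [(40, 60)]})
        assert va.filter_snps([cand], {"chr": track}, mask) == []

    def test_low_support_fails_quality(self):
        cand = va.SnpCandidate("chr", 50, "A", "G")
        track = _track(100, 100, "G", 1, 50)  # 1 of 100 reads supports alt
        assert va.filter_snps([cand], {"chr": track}, va.RepeatMask()) == []

    @given(min_depth=st.integers(0, 60), min_quality=st.floats(0, 60))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_retained_set_shrinks_as_thresholds_rise(self, min_depth, min_quality):
        cands = [va.SnpCandidate("chr", p, "A", "G") for p in (10, 30, 50, 70)]
        track = DepthTrack("chr", np.zeros(100, np.int32),
                           np.zeros((4, 100), np.uint32))
        for p, d, a in [(10, 5, 5), (30, 15, 14), (50, 40, 39), (70, 60, 30)]:
            track.depth[p - 1] = d
            track.base_counts[2, p - 1] = a
        base = {(r.replicon, r.genome_pos) for r in va.filter_snps(
            cands, {"chr": track}, va.RepeatMask(),
            min_quality=min_quality, min_depth=min_depth)}
        tighter = {(r.replicon, r.genome_pos) for r in va.filter_snps(
            cands, {"chr": track}, va.RepeatMask(),
            min_quality=min_quality + 5, min_depth=min_depth + 5)}
        assert tighter <= base


class TestCallQuality:
    def test_high_support_exceeds_q30(self):
        # >= 95% support at any depth passing the depth filter gives Q >= 30
        for depth in (11, 20, 50, 100):
            alt = int(np.ceil(0.95 * depth))
            assert va.call_quality(depth, alt) >= 30

    def test_zero_support_zero_quality(self):
        assert va.call_quality(50, 0) == 0.0


class TestCatalog:
    def test_packaged_catalog_tallies(self):
        from importlib import resources

        path = resources.files("gutstab.data") / "snp_catalog.tsv"
        summary = va.tally_catalog(va.load_catalog(path))
        assert summary.total == 19
        assert summary.by_type[effects.SYNONYMOUS] == 7
        assert summary.by_type[effects.NON_SYNONYMOUS] == 9
        assert summary.by_type[effects.NONSENSE] == 2
        assert summary.by_type[effects.INTERGENIC] == 1
        assert summary.distinct_genes == 18
        assert summary.genes_with_cog == 12
        assert summary.genes_with_ko == 11
        assert summary.distinct_pathways == 9

    def test_empty_catalog_all_zero(self):
        summary = va.tally_catalog([])
        assert summary.total == 0
        assert summary.distinct_genes == 0
        assert summary.distinct_pathways == 0

    def test_malformed_mut_type_reports_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\t".join(va.CATALOG_COLUMNS) + "\n"
                        "SNP01\t123\tweird\tA-G\t-\t-\t-\t-\t-\t-\n")
        with pytest.raises(va.CatalogError, match="row 2"):
            va.load_catalog(path)

    def test_non_integer_position_reports_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\t".join(va.CATALOG_COLUMNS) + "\n"
                        "SNP01\tabc\tSyn\tA-G\tV1V\tg1\tx\t-\t-\t-\n")
        with pytest.raises(va.CatalogError, match="row 2"):
            va.load_catalog(path)

    def test_roundtrip_write_load(self, tmp_path):
        from importlib import resources

        path = resources.files("gutstab.data") / "snp_catalog.tsv"
        records = va.load_catalog(path)
        out = tmp_path / "out.tsv"
        va.write_catalog(records, out)
        back = va.load_catalog(out)
        assert [(r.snp_id, r.genome_pos, r.mut_type, r.pathways)
                for r in back] == \
               [(r.snp_id, r.genome_pos, r.mut_type, r.pathways)
                for r in records]

    def test_vcf_export_wellformed(self, tmp_path):
        from importlib import resources

        records = va.load_catalog(resources.files("gutstab.data") / "snp_catalog.tsv")
        out = tmp_path / "out.vcf"
        va.write_vcf(records, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        body = [l for l in lines if not l.startswith("#")]
        assert len(body) == 19
        assert all(len(l.split("\t")) == 8 for l in body)
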