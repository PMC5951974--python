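"""SNP identification, filtering, effect annotation, and the catalog.

Candidates come from mismatch columns of one-to-one contig-vs-reference
alignment blocks. Three filters are then applied, all with strict
inequalities: call quality > 20, supporting read depth > 10, and position not
inside a repetitive region (defined by genome self-alignment at >= 95%
identity over >= 100 bp). Effects are classified against the bacterial
genetic code (translation table 11).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import binom

from . import effects
from .homology import AlignmentHit, DepthTrack, KmerIndex, local_align
from .seqs import merge_intervals
from .synthgenome import GeneModel, ReferenceGenome

CATALOG_COLUMNS = [
    "SNP_ID", "Genome_pos", "Mut_type", "Mut_base", "Mut_pro",
    "Ref_Gene", "Product", "COG_categories", "KO_No.", "Pathway_No.",
]

_MUT_TYPE_TOKENS = {
    "syn": effects.SYNONYMOUS,
    "synonymous": effects.SYNONYMOUS,
    "non-syn": effects.NON_SYNONYMOUS,
    "nonsyn": effects.NON_SYNONYMOUS,
    "non-synonymous": effects.NON_SYNONYMOUS,
    "nonsense": effects.NONSENSE,
    "intergenic": effects.INTERGENIC,
}

_EMPTY_TOKENS = {"", "-", "–", "—", "nan", "none"}


class CatalogError(ValueError):
    pass


@dataclass
class SnpCandidate:
    replicon: str
    pos: int  # 1-based reference coordinate
    ref: str
    alt: str


@dataclass
class SnpRecord:
    snp_id: str
    replicon: str
    genome_pos: int
    mut_type: str
    ref_base: str
    alt_base: str
    protein_change: str = ""
    gene_id: str = ""
    product: str = ""
    cog: str | None = None
    ko: str | None = None
    pathways: list[str] | None = None
    depth: int = 0
    quality: float = 0.0
    verified: bool | None = None  # Sanger-style confirmation passthrough


@dataclass
class RepeatMask:
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def contains(self, replicon: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals.get(replicon, []))

    def total_masked(self) -> int:
        return sum(e - s + 1 for ivs in self.intervals.values() for s, e in ivs)


# ---------------------------------------------------------------------------
# raw calling


def select_one_to_one_blocks(
    hits: list[AlignmentHit], max_overlap: int = 20
) -> list[AlignmentHit]:
    """Greedy mutually-best block selection (a delta-filter analog).

    Hits are taken by descending score; a hit is rejected when it overlaps an
    accepted hit by more than ``max_overlap`` bp on either the query axis
    (same query sequence) or the subject axis (same replicon).
    """
    accepted: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.query_id, h.s_start)):
        ok = True
        for a in accepted:
            if a.query_id == hit.query_id:
                ov = (min(a.q_end, hit.q_end) - max(a.q_start, hit.q_start) + 1)
                if ov > max_overlap:
                    ok = False
                    break
            if a.subject_id == hit.subject_id:
                ov = (min(a.s_end, hit.s_end) - max(a.s_start, hit.s_start) + 1)
                if ov > max_overlap:
                    ok = False
                    break
        if ok:
            accepted.append(hit)
    return accepted


def call_raw_snps(
    contigs: list[tuple[str, str]],
    reference: dict[str, str] | KmerIndex,
    hits: list[AlignmentHit] | None = None,
    min_identity: float = 90.0,
    max_evalue: float = 1e-5,
    edge_buffer: int = 10,
) -> list[SnpCandidate]:
    """Candidate SNPs from mismatch columns of one-to-one alignment blocks.

    Indel columns are ignored (substitutions only); candidates seen in more
    than one block are deduplicated by (replicon, position, alleles).
    Mismatch columns within ``edge_buffer`` bp of a block boundary are
    discarded: block edges sit at contig breaks and deletion junctions, where
    extension over chance matches manufactures spurious columns.
    """
    index = reference if isinstance(reference, KmerIndex) else KmerIndex(reference)
    if hits is None:
        hits = []
        for name, seq in contigs:
            hits.extend(local_align(seq, index, min_identity=min_identity,
                                    max_evalue=max_evalue, query_id=name))
    blocks = select_one_to_one_blocks(hits)
    seen = set()
    out: list[SnpCandidate] = []
    for block in blocks:
        for q_pos, s_pos, q_base, s_base in block.mismatch_columns:
            if (min(q_pos - block.q_start, block.q_end - q_pos) < edge_buffer
                    or min(s_pos - block.s_start, block.s_end - s_pos) < edge_buffer):
                continue
            key = (block.subject_id, s_pos, s_base, q_base)
            if key in seen or q_base not in "ACGT" or s_base not in "ACGT":
                continue
            seen.add(key)
            out.append(SnpCandidate(block.subject_id, s_pos, s_base, q_base))
    out.sort(key=lambda c: (c.replicon, c.pos, c.alt))
    return out


# ---------------------------------------------------------------------------
# repeat mask


def build_repeat_mask(
    reference: ReferenceGenome | dict[str, str],
    min_identity: float = 95.0,
    min_length: int = 100,
) -> RepeatMask:
    """Mask positions lying in any non-trivial genome self-alignment hit
    (>= 95% identity over >= 100 bp), which captures multi-copy rRNA operons
    and plasmid/chromosome homologous segments."""
    seqs = reference.sequences() if hasattr(reference, "sequences") else dict(reference)
    index = KmerIndex(seqs)
    mask: dict[str, list[tuple[int, int]]] = {rid: [] for rid in seqs}
    for rid in sorted(seqs):
        hits = local_align(seqs[rid], index, min_identity=0.0, max_evalue=1e-5,
                           query_id=rid)
        for h in hits:
            trivial = (h.subject_id == rid and h.strand == "+"
                       and h.q_start == h.s_start and h.q_end == h.s_end)
            if trivial:
                continue
            if h.identity >= min_identity and h.aligned_length >= min_length:
                mask[h.subject_id].append((h.s_start, h.s_end))
                mask[rid].append((h.q_start, h.q_end))
    return RepeatMask({rid: merge_intervals(ivs) for rid, ivs in mask.items() if ivs})


# ---------------------------------------------------------------------------
# quality and filtering


def call_quality(depth: int, alt_count: int, base_error_rate: float = 0.01,
                 cap: float = 60.0) -> float:
    """Phred-scaled call confidence: probability of >= alt_count mismatching
    reads among ``depth`` under the base-calling error null (rate 0.01)."""
    if depth <= 0 or alt_count <= 0:
        return 0.0
    p = float(binom.sf(alt_count - 1, depth, base_error_rate))
    if p <= 0:
        return cap
    return min(cap, -10.0 * math.log10(p))


def filter_snps(
    candidates: list[SnpCandidate],
    depth_tracks: dict[str, DepthTrack],
    repeat_mask: RepeatMask,
    reference: ReferenceGenome | None = None,
    min_quality: float = 20.0,
    min_depth: int = 10,
) -> list[SnpRecord]:
    """Apply the three filters (quality > 20, depth > 10, non-repeat; all
    strict) and annotate survivors into full records."""
    out: list[SnpRecord] = []
    n = 0
    for cand in candidates:
        track = depth_tracks.get(cand.replicon)
        if track is None:
            continue
        depth = int(track.depth[cand.pos - 1])
        alt_count = int(track.base_counts["ACGT".index(cand.alt), cand.pos - 1])
        quality = call_quality(depth, alt_count)
        if depth <= min_depth or quality <= min_quality:
            continue
        if repeat_mask.contains(cand.replicon, cand.pos):
            continue
        n += 1
        if reference is not None:
            rec = annotate_effect(cand, reference, snp_id=f"SNP{n:02d}")
        else:
            rec = SnpRecord(f"SNP{n:02d}", cand.replicon, cand.pos,
                            effects.INTERGENIC, cand.ref, cand.alt)
        rec.depth = depth
        rec.quality = round(quality, 1)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# effect annotation


def annotate_effect(
    candidate: SnpCandidate,
    reference: ReferenceGenome,
    gene_models: list[GeneModel] | None = None,
    snp_id: str = "SNP",
) -> SnpRecord:
    """Classify a substitution as synonymous / non-synonymous / nonsense /
    intergenic and format the protein change (stop written as 'X')."""
    seq = reference.replicon(candidate.replicon).sequence
    if not (1 <= candidate.pos <= len(seq)):
        raise ValueError(f"position {candidate.pos} beyond {candidate.replicon}")
    genes = gene_models if gene_models is not None else reference.gene_models
    gene = next((g for g in genes
                 if g.replicon_id == candidate.replicon
                 and g.start <= candidate.pos <= g.end), None)
    if gene is None:
        return SnpRecord(snp_id, candidate.replicon, candidate.pos,
                         effects.INTERGENIC, candidate.ref, candidate.alt)
    eff = effects.classify_in_gene(
        seq[gene.start - 1 : gene.end], gene.start, gene.end, gene.strand,
        candidate.pos, candidate.ref, candidate.alt)
    return SnpRecord(
        snp_id, candidate.replicon, candidate.pos, eff.mut_type,
        candidate.ref, candidate.alt, protein_change=eff.protein_change,
        gene_id=gene.gene_id, product=gene.product, cog=gene.cog, ko=gene.ko,
        pathways=list(gene.pathways) if gene.pathways else None)


# ---------------------------------------------------------------------------
# catalog I/O and tallies


def _norm_empty(value) -> str:
    s = str(value).strip()
    return "" if s.lower() in _EMPTY_TOKENS else s


def load_catalog(path) -> list[SnpRecord]:
    """Read a catalog TSV with the standard column set into records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after header
        token = _norm_empty(row["Mut_type"]).lower()
        if token not in _MUT_TYPE_TOKENS:
            raise CatalogError(f"row {rownum}: bad Mut_type {row['Mut_type']!r}")
        mut_type = _MUT_TYPE_TOKENS[token]
        try:
            pos = int(row["Genome_pos"])
        except ValueError as exc:
            raise CatalogError(
                f"row {rownum}: non-integer Genome_pos {row['Genome_pos']!r}"
            ) from exc
        bases = _norm_empty(row["Mut_base"])
        ref, _, alt = bases.partition("-")
        pathways_raw = _norm_empty(row["Pathway_No."])
        pathways = _parse_pathways(pathways_raw) if pathways_raw else None
        records.append(SnpRecord(
            snp_id=row["SNP_ID"], replicon="chr", genome_pos=pos,
            mut_type=mut_type, ref_base=ref, alt_base=alt,
            protein_change=_norm_empty(row["Mut_pro"]),
            gene_id=_norm_empty(row["Ref_Gene"]),
            product=_norm_empty(row["Product"]),
            cog=_norm_empty(row["COG_categories"]) or None,
            ko=_norm_empty(row["KO_No."]) or None,
            pathways=pathways))
    return records


def _parse_pathways(text: str) -> list[str]:
    """Extract pathway ids from bracketed lists like
    'Metabolism[PATH:ko00052,ko00520]'."""
    import re

    return re.findall(r"ko\d+", text)


def write_catalog(records: list[SnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in records:
            token = {"synonymous": "Syn", "non-synonymous": "Non-syn",
                     "nonsense": "Nonsense", "intergenic": "Intergenic"}[r.mut_type]
            pw = ("PATH:" + ",".join(r.pathways)) if r.pathways else "-"
            fh.write("\t".join([
                r.snp_id, str(r.genome_pos), token,
                f"{r.ref_base}-{r.alt_base}", r.protein_change or "-",
                r.gene_id or "-", r.product or "-", r.cog or "-",
                r.ko or "-", pw]) + "\n")


@dataclass
class CatalogSummary:
    total: int
    by_type: dict[str, int]
    distinct_genes: int  # among non-intergenic records
    genes_with_cog: int
    genes_with_ko: int
    distinct_pathways: int


def tally_catalog(records: list[SnpRecord]) -> CatalogSummary:
    by_type = {t: 0 for t in effects.EFFECT_CLASSES}
    genes, cog_genes, ko_genes, pathways = set(), set(), set(), set()
    for r in records:
        by_type[r.mut_type] += 1
        if r.mut_type != effects.INTERGENIC and r.gene_id:
            genes.add(r.gene_id)
            if r.cog:
                cog_genes.add(r.gene_id)
            if r.ko:
                ko_genes.add(r.gene_id)
        if r.pathways:
            pathways.update(r.pathways)
    return CatalogSummary(
        total=len(records), by_type=by_type, distinct_genes=len(genes),
        genes_with_cog=len(cog_genes), genes_with_ko=len(ko_genes),
        distinct_pathways=len(pathways))


def write_vcf(records: list[SnpRecord], path, reference_name: str = "reference") -> None:
    """Minimal VCF 4.2 export of a catalog (interoperability convenience)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda x: (x.replicon, x.genome_pos)):
            info = f"DP={r.depth};EFF={r.mut_type}"
            fh.write(f"{r.replicon}\t{r.genome_pos}\t{r.snp_id}\t{r.ref_base}\t"
                     f"{r.alt_base}\t{r.quality:.0f}\t.\t{info}\n")
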