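"""Core/accessory genome delineation across a cohort of assemblies.

Core sequence is what every strain (and the reference) shares: per-strain
contig alignments at >= 90% identity and e-value < 1e-5 mark reference
coverage, and the core is the intersection over all strains. Contig bases
that align into non-core reference regions, or align nowhere, are
strain-specific; after single-linkage deduplication (identity >= 90% over
>= 85% of the shorter sequence) the survivors form the non-redundant
accessory genome, each assigned a source (plasmid-born, chromosome-
homologous, or novel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology import AlignmentHit, KmerIndex, local_align
from .seqs import complement_intervals, interval_length, merge_intervals
from .synthgenome import ReferenceGenome

MIN_FRAGMENT = 200  # smallest reportable strain-specific fragment, bp

PLASMID_BORN = "plasmid-born"
CHROMOSOME_HOMOLOGOUS = "chromosome-homologous"
NOVEL = "novel"


@dataclass
class StrainSpecificSeq:
    strain_id: str
    fragment_id: str
    contig_id: str
    start: int  # 1-based on the contig
    end: int
    sequence: str


@dataclass
class AccessoryFragment:
    fragment_id: str
    sequence: str
    member_strains: list[str]
    source: str = NOVEL
    source_replicon: str | None = None
    # best reference hit even when below threshold: (replicon, start, end, identity)
    best_reference_hit: tuple[str, int, int, float] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CoreDelineation:
    core_intervals: dict[str, list[tuple[int, int]]]  # on the reference
    strain_specific: dict[str, list[StrainSpecificSeq]]  # per strain
    per_strain_coverage: dict[str, dict[str, list[tuple[int, int]]]]
    # bookkeeping for the partition invariant, per strain:
    partition: dict[str, dict[str, int]] = field(default_factory=dict)

    def core_length(self) -> int:
        return sum(interval_length(ivs) for ivs in self.core_intervals.values())


def _project_to_query(hit: AlignmentHit, ref_ivs: list[tuple[int, int]]):
    """Project reference intervals through a hit onto query coordinates.

    Uses the colinear approximation (exact for ungapped hits; off by at most
    the gap bases otherwise, which is within the stage's stated boundary
    tolerance).
    """
    out = []
    for s, e in ref_ivs:
        lo, hi = max(s, hit.s_start), min(e, hit.s_end)
        if lo > hi:
            continue
        if hit.strand == "+":
            q_lo = hit.q_start + (lo - hit.s_start)
            q_hi = hit.q_start + (hi - hit.s_start)
        else:
            q_hi = hit.q_end - (lo - hit.s_start)
            q_lo = hit.q_end - (hi - hit.s_start)
        out.append((max(q_lo, hit.q_start), min(q_hi, hit.q_end)))
    return out


def delineate_core(
    contigs_by_strain: dict[str, list[tuple[str, str]]],
    reference: ReferenceGenome | dict[str, str],
    min_identity: float = 90.0,
    max_evalue: float = 1e-5,
    min_fragment: int = MIN_FRAGMENT,
) -> CoreDelineation:
    """Split every contig base into core vs strain-specific sequence."""
    ref_seqs = (reference.sequences() if hasattr(reference, "sequences")
                else dict(reference))
    index = KmerIndex(ref_seqs)
    lengths = {rid: len(s) for rid, s in ref_seqs.items()}

    hits_by_strain: dict[str, dict[str, list[AlignmentHit]]] = {}
    coverage: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for strain in sorted(contigs_by_strain):
        cov = {rid: [] for rid in ref_seqs}
        per_contig: dict[str, list[AlignmentHit]] = {}
        for name, seq in contigs_by_strain[strain]:
            hits = local_align(seq, index, min_identity=min_identity,
                               max_evalue=max_evalue, query_id=name)
            per_contig[name] = hits
            for h in hits:
                cov[h.subject_id].append((h.s_start, h.s_end))
        hits_by_strain[strain] = per_contig
        coverage[strain] = {rid: merge_intervals(ivs) for rid, ivs in cov.items()}

    # core = reference regions covered by every strain
    core: dict[str, list[tuple[int, int]]] = {}
    for rid, L in lengths.items():
        missing: list[tuple[int, int]] = []
        for strain in coverage:
            missing.extend(complement_intervals(coverage[strain][rid], L))
        core[rid] = complement_intervals(merge_intervals(missing), L)

    specific: dict[str, list[StrainSpecificSeq]] = {}
    partition: dict[str, dict[str, int]] = {}
    for strain, per_contig in hits_by_strain.items():
        frags: list[StrainSpecificSeq] = []
        total = core_len = dropped = 0
        fi = 0
        for name, seq in contigs_by_strain[strain]:
            L = len(seq)
            total += L
            core_on_contig: list[tuple[int, int]] = []
            for h in per_contig[name]:
                core_on_contig.extend(_project_to_query(h, core[h.subject_id]))
            core_on_contig = merge_intervals(core_on_contig)
            core_len += interval_length(core_on_contig)
            for s, e in complement_intervals(core_on_contig, L):
                if e - s + 1 < min_fragment:
                    dropped += e - s + 1
                    continue
                fi += 1
                frags.append(StrainSpecificSeq(
                    strain, f"{strain}_sf{fi:03d}", name, s, e, seq[s - 1 : e]))
        specific[strain] = frags
        partition[strain] = {
            "total": total, "core": core_len,
            "specific": sum(len(f.sequence) for f in frags), "dropped": dropped}
    return CoreDelineation(core, specific, coverage, partition)


# ---------------------------------------------------------------------------
# accessory deduplication


def _similar(a: str, b: str, min_identity: float, min_length_fraction: float) -> bool:
    """Joint criterion: identity >= 90% over >= 85% of the shorter sequence."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    hits = local_align(short, long_, min_identity=min_identity, max_evalue=10.0)
    for h in hits:
        if (h.q_end - h.q_start + 1) >= min_length_fraction * len(short):
            return True
    return False


def build_accessory(
    strain_specific: dict[str, list[StrainSpecificSeq]],
    min_identity: float = 90.0,
    min_length_fraction: float = 0.85,
) -> list[AccessoryFragment]:
    """Single-linkage clustering of strain-specific sequences into a
    non-redundant accessory genome.

    The representative of each cluster is its longest member (ties broken
    lexicographically by fragment id); inputs are canonically ordered first,
    so the result is invariant to strain input order.
    """
    frags = sorted(
        (f for flist in strain_specific.values() for f in flist),
        key=lambda f: (-len(f.sequence), f.fragment_id))
    n = len(frags)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _similar(frags[i].sequence, frags[j].sequence,
                        min_identity, min_length_fraction):
                parent[find(j)] = find(i)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out: list[AccessoryFragment] = []
    for root in sorted(clusters, key=lambda r: (-len(frags[r].sequence),
                                                frags[r].fragment_id)):
        members = clusters[root]
        rep = min(members, key=lambda i: (-len(frags[i].sequence),
                                          frags[i].fragment_id))
        strains = sorted({frags[i].strain_id for i in members})
        out.append(AccessoryFragment(
            fragment_id=f"acc{len(out) + 1:03d}",
            sequence=frags[rep].sequence,
            member_strains=strains))
    return out


def assign_source(
    fragments: list[AccessoryFragment],
    reference: ReferenceGenome,
    min_identity: float = 90.0,
    min_length_fraction: float = 0.85,
    reporting_floor: float = 50.0,
) -> list[AccessoryFragment]:
    """Label each accessory fragment by its best reference placement.

    A fragment mapping at >= 90% identity over >= 85% of its length to a
    plasmid is plasmid-born; to the chromosome only, chromosome-homologous;
    anything else is novel. The best hit is recorded down to the reporting
    floor even when below threshold, so near-threshold homologies (the HGT
    signature) stay visible.
    """
    index = KmerIndex(reference.sequences())
    roles = {r.id: r.role for r in reference.replicons}
    for frag in fragments:
        hits = local_align(frag.sequence, index, min_identity=0.0,
                           max_evalue=10.0, query_id=frag.fragment_id)
        frag.source = NOVEL
        frag.source_replicon = None
        frag.best_reference_hit = None
        best = next((h for h in hits if h.identity >= reporting_floor), None)
        if best is not None:
            frag.best_reference_hit = (
                best.subject_id, best.s_start, best.s_end, round(best.identity, 1))
        placed_plasmid = placed_chrom = None
        for h in hits:  # hits arrive sorted by score descending
            span = h.q_end - h.q_start + 1
            if h.identity >= min_identity and span >= min_length_fraction * frag.length:
                if roles[h.subject_id] == "plasmid":
                    placed_plasmid = placed_plasmid or h
                else:
                    placed_chrom = placed_chrom or h
        if placed_plasmid is not None:  # plasmid placement takes precedence
            frag.source = PLASMID_BORN
            frag.source_replicon = placed_plasmid.subject_id
        elif placed_chrom is not None:
            frag.source = CHROMOSOME_HOMOLOGOUS
            frag.source_replicon = placed_chrom.subject_id
    return fragments


def write_accessory(fragments: list[AccessoryFragment], all_strains: list[str],
                    fasta_path, matrix_path) -> None:
    """Accessory genome as multi-FASTA plus a fragments x strains 0/1 matrix."""
    from .seqs import write_fasta

    write_fasta(fasta_path, [(f.fragment_id, f.sequence) for f in fragments])
    with open(matrix_path, "w") as fh:
        fh.write("fragment_id\t" + "\t".join(all_strains) + "\n")
        for f in fragments:
            row = ["1" if s in f.member_strains else "0" for s in all_strains]
            fh.write(f.fragment_id + "\t" + "\t".join(row) + "\n")


def write_core_bed(core_intervals: dict[str, list[tuple[int, int]]], path) -> None:
    """Core intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for rid in sorted(core_intervals):
            for s, e in core_intervals[rid]:
                fh.write(f"{rid}\t{s - 1}\t{e}\tcore\n")
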