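# Methods

## The analysis model

The package treats a within-host stability survey as an event-recovery
problem. A reference genome `R` (one chromosome, plasmids `p1..p7`) and a set
of derived strains are related by three event types: substitutions on the
chromosome, deletions of plasmid sequence (up to whole-replicon loss), and
insertion of foreign DNA. The analysis stages never see the event ledger;
they must recover it from assemblies (contigs) and paired-end reads, exactly
as a sequencing study would. The synthetic-data generator produces both the
genomes and the ground truth, so recovery can be scored exactly.

## Synthetic genomes

The reference emulates a *Lactobacillus*-scale system reduced to desk size:
a 200-kb chromosome at GC 0.445 and seven plasmids of 5–60 kb (defaults:
20, 15, 8, 12, 6, 10, 9 kb). Protein-coding genes are generated as valid
CDSs — `ATG`, random non-stop codons sampled at the target GC, one stop — on
both strands with 80–300-bp intergenic gaps (~65% coding density at desk
scale). Rejecting the AT-rich stop codons raises coding GC by ~1.4%, so the
codon sampler is nudged down by that amount; realized whole-genome GC lands
within ±0.2% of target across seeds.

Five 2923-bp 23S rRNA copies are written onto the chromosome, each differing
from a master copy by at most one substitution at distinct positions, so
pairwise distance is ≤2 (identity 99.93%, satisfying the >99.9% constraint).
Alternating strands exercise strand handling downstream.

Plasmids p2, p4 and p7 carry segments copied from the chromosome and mutated
to ~96% identity (homologous fractions 0.40 / 0.30 / 0.50). Two forces shaped
the 96% figure: the homology map requires ≥90% identity, while the read
mapper discards ambiguous placements — at 100% identity every read in those
segments would be discarded and an intact plasmid would be mis-called absent.
At 96%, 101-bp reads map uniquely to their true replicon (a read matches its
source exactly and its homolog with ~4 mismatches), yet the segments still
register in the ≥95%-identity repeat mask and the homology map. Replicons are
linear; origin-spanning features are not generated.

### Events

* **Substitutions.** `plan_catalog_snps` searches coding sites whose
  substitution realizes a requested effect class (default mix: 7 synonymous,
  9 non-synonymous, 2 nonsense, 1 intergenic, one gene per coding SNP),
  restricted to non-repeat chromosome sites with a 150-bp margin. Explicit
  specs are validated: the reference base must match and the realized class
  must equal the intent, otherwise planting fails with a diagnostic.
* **Plasmid losses.** Partial loss deletes one contiguous block of the
  requested fraction at a random offset (true PLR recorded as deleted/total);
  complete loss removes the replicon.
* **Acquisition.** The donor fragment is the reference 23S interval
  1215..1823 (609 bp) mutated to 88% identity; a second variant at 97%
  identity to the fragment stands in for the donor species' own gene
  (a synthetic stand-in for an external database entry). 88% rather than 90%:
  local alignment trims a few divergent end columns off any hit, lifting
  recovered identity by 1–2 points, so a fragment planted at exactly 90%
  would often meet the ≥90% core threshold and vanish into the core. At 88%
  the recovered homology sits just under 90% — a near-threshold signature —
  and the fragment robustly stays accessory.

### Reads and contigs

Pairs are 101 bp with normal(350, 35) inserts at 100× by default; pair count
is `depth·L/(2·read_length)` per replicon, fragment starts uniform. Base
errors (default 0) are uniform substitutions; qualities are constant Q40 with
error bases downgraded to Q10 (Phred+33). Contigs partition each replicon at
random breakpoints (normal(20 kb, 5 kb) lengths), never joining replicons,
with optional inter-contig gaps. The simulation driver additionally forces
contig breaks at acquisition junctions: a seed-and-extend aligner (like
BLAST) extends straight through a ~90%-identity insert flanked by exact
sequence (expected score +0.7/column at +1/−2), so an insert embedded
mid-contig would be absorbed into a core alignment. Real de Bruijn assemblers
terminate contigs at exactly such divergent-repeat boundaries; the forced
break emulates that behavior, and is a property of the simulated assembly,
not of the analysis stages (which never see the truth ledger).

What the generator does **not** emulate: indels and rearrangements, GC skew
and codon-usage structure, coverage biases (GC, origin proximity), chimeric
or error-bearing contigs, and real phylogenetic divergence between cohort
strains. Passing recovery tests therefore demonstrate correctness of the
analysis logic under clean conditions (error-free reads, substitution-only
divergence), not robustness to assembly artifacts.

## Alignment engine

Seeding uses exact 15-mers over an index of the subject; seeds are grouped by
diagonal (bands split at diagonal jumps >20) and by query gaps >100 bp,
extended outward ungapped with X-drop 20, and scored. Regions confined to a
single diagonal are scored by direct column comparison; regions with diagonal
spread go through banded global DP with affine gaps (match +1, mismatch −2,
a gap of length g costs 5 + 2g). Identity is matches / alignment columns.
E-values use Karlin–Altschul `E = K·m·n·exp(−λS)` with fixed ungapped
nucleotide parameters λ=1.28, K=0.46 — approximate by design; thresholding
behavior, not BLAST-identical statistics, is the contract. Both strands are
searched; duplicate hits from clusters extending to the same maximal region
are collapsed. On substitution-only test pairs the top hit matches a full
Smith–Waterman oracle (Biopython `PairwiseAligner`, local mode, same scoring)
to within ±1 identity point and 5% of score; the oracle is used only in
tests, never in the pipeline.

The exact-15-mer seeding bounds sensitivity: below ~75–80% identity no seeds
survive and no hit is reported. This matters only to the ANI retention rule
(below).

## Read mapping

Reads are placed by k-mer candidate lookup (k=21, three offsets, both
strands) followed by full-length verification with ≤5 mismatches. A read with
tied best placements at distinct loci is discarded; this deliberately
depresses depth in multi-copy repeats (the rRNA operons), which the repeat
filter of the variant stage then excludes anyway. Per-position depth and
A/C/G/T pileup counts feed breadth, PLR, and call-quality computations.

## Variant stage

One-to-one blocks are selected greedily by score, rejecting hits overlapping
an accepted hit by >20 bp on either axis (a delta-filter analog). Mismatch
columns become candidates; columns within 10 bp of a block edge are dropped —
block edges sit at contig breaks and deletion junctions, where X-drop
extension over chance matches and short-overhang read placements manufacture
spurious columns. Call quality is the Phred-scaled binomial tail probability
of observing the alt-supporting read count under a 1% base-error null (≥95%
support at any depth passing the >10 filter gives Q≥30; capped at Q60). The
published thresholds are strict inequalities: quality > 20, depth > 10,
position not repeat-masked. The repeat mask comes from genome self-alignment:
any non-trivial hit at ≥95% identity over ≥100 bp masks both copies.

"Quality > 20" in this kind of survey is ambiguous between raw base quality
and call quality; call quality is adopted because it is computable from both
inputs (contigs and reads) and degrades gracefully with mixed support.

## Pan-genome

Core is defined cohort-wide: reference regions covered by **every** strain at
≥90% identity, e-value <1e-5. A region absent from even one strain (a lost
plasmid segment) is non-core, so the surviving strains' copies of it become
strain-specific — this is what makes most accessory fragments plasmid-born,
and the chromosome-homologous remainders of partially-lost plasmids stay
core because reads/contigs of every strain still cover the chromosome copy.
Strain-specific sequence is split at core boundaries, fragments <200 bp are
dropped as alignment-edge slivers, and single-linkage clustering at ≥90%
identity over ≥85% of the *shorter* sequence (the shorter-sequence reading
prevents long fragments from absorbing unrelated short ones) yields the
non-redundant accessory genome. Representatives are the longest members, ties
broken lexicographically; inputs are canonically ordered, so clustering is
invariant to strain order.

## Plasmid dynamics

Breadth thresholds are strict: >0.8 present, <0.2 absent, and the undefined
middle band is an explicit `ambiguous` call rather than a forced binary.
Missing intervals are maximal zero-depth runs ≥300 bp (shorter runs are
finite-coverage noise, e.g. replicon ends); PLR is their merged length over
the plasmid length. The loss classifier is total over [0,1]: none (0),
<70%, 70–80%, 80–90%, 90–100% (an added bin so the partition is exhaustive),
complete (1.0); bins are left-closed. Entire-loss confirmation — the in-silico
analog of plasmid-specific-primer PCR — requires the whole-plasmid call to be
absent *and* plasmid-specific regions (plasmid minus homologous segments) to
be essentially uncovered (breadth ≤0.02, not the 0.2 absence cutoff: a PLR
0.85 partial loss leaves its retained specific sequence deeply covered and
must not be "confirmed entire"). A plasmid with no specific region returns an
explicit indeterminate status.

## ANI and screening

Fragment ANI cuts the query into consecutive 1020-bp windows, aligns each to
the subject, retains windows aligning over ≥70% of their length at ≥30%
identity, and averages retained identities; no retained window yields an
explicitly undefined ANI (never 0). Given the seeding floor, retention in
practice requires ~≥75–80% identity — the same qualitative floor as
BLAST-based fragment ANI. Screening retains isolates at ANI ≥95 (one-way,
isolate → reference); undefined ANI is always excluded, with a reason.

The mutation-rate bound divides the largest per-strain SNP count by an
explicit generation count. The generation count is never inferred: the
bundled example uses 690 generations with ≤2 substitutions per strain, which
reproduces the canonical 0.0029 changes/generation bound against the 0.0033
spontaneous benchmark; 690 is documented as an assumption, not a measurement.

## Problem sizes and determinism

Desk scale (the default, used by the analysis drivers and the acceptance
script) is a 200-kb chromosome with 76 kb of plasmids at 100×, ~140k read
pairs per strain; unit tests use 24–60-kb genomes. All randomness flows
through integer seeds (per-stage seeds derived by hashing), and identical
(config, seed) pairs give byte-identical FASTA/FASTQ and reports. Packaged
fixtures are text: the machine-readable SNP catalog and a synthetic cohort
manifest reproducing the study-scale screening bookkeeping (108 isolates,
one subject's 16 isolates below the ANI cutoff).

## Known limitations

* Substitutions only: no indel or rearrangement calling (short-read surveys
  of this design cannot see rearrangements either).
* The aligner is not a BLAST replacement: e-values are approximate, and
  sensitivity ends near 75–80% identity.
* Plasmid copy-number is not modeled; depth ratios are not interpreted.
* The breadth-in-(0.2, 0.8) band is surfaced, not resolved; downstream
  consumers must decide what ambiguous presence means for their question.
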