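"""Plasmid presence/absence calling, the plasmid loss ratio (PLR), entire-loss
confirmation, and acquired-fragment (HGT) flagging.

Presence follows coverage breadth with strict thresholds — breadth > 0.8 is
present, < 0.2 absent — and the undefined middle band is surfaced as an
explicit ``ambiguous`` call rather than forced to a binary. PLR is the
missing length divided by the plasmid length; loss classes are the four
reported types (complete, 80-90%, 70-80%, <70%) plus a 90-100% bin so the
classifier is total over [0, 1]. Entire loss is confirmed in silico via
plasmid-specific regions (the plasmid minus its chromosome-homologous
segments), mirroring a PCR confirmation with plasmid-specific primers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .homology import DepthTrack, KmerIndex, local_align
from .pangenome import NOVEL, AccessoryFragment
from .seqs import complement_intervals, merge_intervals
from .synthgenome import ReferenceGenome

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"

LOSS_NONE = "none"
LOSS_LT70 = "<70%"
LOSS_70_80 = "70-80%"
LOSS_80_90 = "80-90%"
LOSS_90_100 = "90-100%"
LOSS_COMPLETE = "complete"

MIN_ZERO_RUN = 300  # zero-depth runs shorter than this are coverage noise


class Confirmation(enum.Enum):
    CONFIRMED = "confirmed"
    NOT_CONFIRMED = "not_confirmed"
    INDETERMINATE = "indeterminate"


@dataclass
class PresenceCall:
    strain_id: str
    target_id: str
    coverage_breadth: float
    mean_depth: float
    call: str


@dataclass
class PlasmidLossReport:
    strain_id: str
    plasmid_id: str
    breadth: float
    mean_depth: float
    plr: float
    loss_class: str
    confirmed_entire_loss: Confirmation
    missing_intervals: list[tuple[int, int]]


@dataclass
class HgtCandidate:
    fragment_id: str
    length: int
    carrier_strains: list[str]
    best_reference_homolog: tuple[str, str, float] | None  # (replicon, feature, identity%)
    best_donor_hit: tuple[str, float] | None  # (donor id, identity%)


# ---------------------------------------------------------------------------
# coverage statistics


def coverage_breadth(track: DepthTrack,
                     intervals: list[tuple[int, int]] | None = None) -> float:
    """Fraction of positions (within ``intervals``, or the whole replicon)
    covered by at least one read."""
    if intervals is None:
        d = track.depth
        return float(np.count_nonzero(d)) / len(d) if len(d) else 0.0
    total = covered = 0
    for s, e in merge_intervals(intervals):
        seg = track.depth[s - 1 : e]
        total += len(seg)
        covered += int(np.count_nonzero(seg))
    return covered / total if total else 0.0


def mean_depth(track: DepthTrack) -> float:
    return float(track.depth.mean()) if len(track.depth) else 0.0


def call_presence(breadth: float) -> str:
    if breadth > 0.8:
        return PRESENT
    if breadth < 0.2:
        return ABSENT
    return AMBIGUOUS


def missing_intervals(track: DepthTrack, min_run: int = MIN_ZERO_RUN
                      ) -> list[tuple[int, int]]:
    """Maximal zero-depth runs of at least ``min_run`` bp (1-based)."""
    zero = track.depth == 0
    if not zero.any():
        return []
    padded = np.concatenate([[False], zero, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s) + 1, int(e)) for s, e in zip(starts, ends)
            if e - s >= min_run]


# ---------------------------------------------------------------------------
# PLR


def compute_plr(missing: list[tuple[int, int]], plasmid_length: int) -> float:
    if plasmid_length <= 0:
        raise ValueError("plasmid length must be positive")
    merged = merge_intervals(missing)
    lost = sum(e - s + 1 for s, e in merged)
    return min(1.0, lost / plasmid_length)


def classify_loss(plr: float) -> str:
    """Total, deterministic partition of [0, 1] into loss classes."""
    if not (0.0 <= plr <= 1.0):
        raise ValueError("PLR must lie in [0, 1]")
    if plr == 0.0:
        return LOSS_NONE
    if plr == 1.0:
        return LOSS_COMPLETE
    if plr >= 0.9:
        return LOSS_90_100
    if plr >= 0.8:
        return LOSS_80_90
    if plr >= 0.7:
        return LOSS_70_80
    return LOSS_LT70


def confirm_entire_loss(
    track: DepthTrack,
    plasmid_id: str,
    reference: ReferenceGenome,
    max_specific_breadth: float = 0.02,
) -> Confirmation:
    """In-silico analog of PCR confirmation with plasmid-specific primers.

    Entire loss is confirmed when the whole-plasmid call is absent AND the
    plasmid-specific regions (plasmid minus chromosome-homologous segments)
    are essentially uncovered. The specific-region threshold is near zero
    rather than the 0.2 absence cutoff: a high partial loss (e.g. PLR 0.85)
    still leaves its retained region deeply covered, and any surviving
    plasmid-specific sequence would yield a primer product — so confirmation
    must imply a complete loss. A plasmid that is entirely
    chromosome-homologous has no specific region, so confirmation is
    indeterminate.
    """
    L = reference.replicon(plasmid_id).length
    hom = [(h.plasmid_start, h.plasmid_end) for h in reference.homology_map
           if h.plasmid_id == plasmid_id]
    specific = complement_intervals(hom, L)
    if not specific:
        return Confirmation.INDETERMINATE
    whole_call = call_presence(coverage_breadth(track))
    specific_breadth = coverage_breadth(track, specific)
    if whole_call == ABSENT and specific_breadth <= max_specific_breadth:
        return Confirmation.CONFIRMED
    return Confirmation.NOT_CONFIRMED


def plasmid_report(
    strain_id: str,
    tracks: dict[str, DepthTrack],
    reference: ReferenceGenome,
    min_zero_run: int = MIN_ZERO_RUN,
) -> list[PlasmidLossReport]:
    """Per-plasmid breadth, depth, PLR, loss class and confirmation status."""
    out = []
    for plasmid in reference.plasmids:
        track = tracks[plasmid.id]
        miss = missing_intervals(track, min_zero_run)
        plr = compute_plr(miss, plasmid.length)
        breadth = coverage_breadth(track)
        # a fully uncovered plasmid is a complete loss even if edge effects
        # leave plr fractionally under 1 — the whole-plasmid call decides
        if call_presence(breadth) == ABSENT and plr >= 0.98:
            plr = 1.0
        out.append(PlasmidLossReport(
            strain_id=strain_id, plasmid_id=plasmid.id,
            breadth=round(breadth, 4), mean_depth=round(mean_depth(track), 2),
            plr=round(plr, 4), loss_class=classify_loss(round(plr, 4)),
            confirmed_entire_loss=confirm_entire_loss(track, plasmid.id, reference),
            missing_intervals=miss))
    return out


# ---------------------------------------------------------------------------
# acquisitions (HGT)


def _homolog_feature(reference: ReferenceGenome, replicon: str,
                     start: int, end: int) -> str:
    """Human-readable label for the reference feature a hit overlaps."""
    for rid, s, e, _ in reference.rrna_copies:
        if rid == replicon and start <= e and end >= s:
            return "23S_rRNA"
    for g in reference.gene_models:
        if g.replicon_id == replicon and start <= g.end and end >= g.start:
            return g.gene_id
    return f"{replicon}:{start}-{end}"


def detect_acquisitions(
    fragments: list[AccessoryFragment],
    reference: ReferenceGenome,
    donor_db: dict[str, str] | None = None,
    reporting_floor: float = 50.0,
) -> list[HgtCandidate]:
    """Flag novel accessory fragments as putative horizontally acquired DNA.

    Every novel fragment carried by at least one strain becomes a candidate;
    its best reference homolog (at any identity >= the reporting floor) and,
    when a donor database is supplied, its best donor hit are reported. No
    taxonomic inference is attempted.
    """
    donor_index = KmerIndex(donor_db) if donor_db else None
    out = []
    for frag in fragments:
        if frag.source != NOVEL or not frag.member_strains:
            continue
        homolog = None
        if frag.best_reference_hit is not None:
            rid, s, e, ident = frag.best_reference_hit
            if ident >= reporting_floor:
                homolog = (rid, _homolog_feature(reference, rid, s, e), ident)
        donor_hit = None
        if donor_index is not None:
            hits = local_align(frag.sequence, donor_index, min_identity=0.0,
                               max_evalue=10.0, query_id=frag.fragment_id)
            hits = [h for h in hits if h.identity >= reporting_floor]
            if hits:
                donor_hit = (hits[0].subject_id, round(hits[0].identity, 1))
        out.append(HgtCandidate(
            fragment_id=frag.fragment_id, length=frag.length,
            carrier_strains=list(frag.member_strains),
            best_reference_homolog=homolog, best_donor_hit=donor_hit))
    return out


def write_plasmid_report(reports: list[PlasmidLossReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tplasmid\tbreadth\tmean_depth\tplr\tloss_class\tconfirmed\n")
        for r in reports:
            fh.write(f"{r.strain_id}\t{r.plasmid_id}\t{r.breadth:.4f}\t"
                     f"{r.mean_depth:.2f}\t{r.plr:.4f}\t{r.loss_class}\t"
                     f"{r.confirmed_entire_loss.value}\n")
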