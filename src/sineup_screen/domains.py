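"""SINEUP functional-domain annotation and deletion-mutant design.

A SINEUP antisense lncRNA carries two modular domains: a binding domain
(BD), the antisense region complementary to the sense mRNA around its
translation-initiation site, and an effector domain (ED), an embedded
inverted SINE-derived region that drives the translational up-regulation.
This module locates both on a candidate pair, maps them into mature
transcript coordinates, and emits the wild-type and domain-deletion
(dBD/dED) construct sequences used to test domain necessity.

The BD is defined as the maximal contiguous run of the per-base exonic
intersection of the two transcripts that contains at least one base of the
sense start codon: a single contiguous antisense block anchored on the
TIS, which makes its length well-defined even when the two exon sets
intersect in several places. The ED is the exon-clipped union of the
embedded TE hits, merged when they overlap or abut (nested monomer-in-Alu
configurations collapse to one region); when several disjoint clusters
exist, the one nearest the transcript 3' end is the ED and the rest are
reported as secondary. "Near the 3' end" is reported as a distance, never
enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation_io import (
    GenomicInterval,
    TranscriptModel,
    exonic_intersection,
    intersect_runs,
    merge_runs,
    spliced_sequence,
    start_codon_intervals,
)
from .repeats import EmbeddedTE


class DomainError(ValueError):
    """Raised when a domain cannot be defined on the given pair."""


@dataclass
class EffectorDomain:
    ed_genomic: GenomicInterval
    ed_len_nt: int
    ed_members: list[EmbeddedTE]
    ed_dist_to_3prime_nt: int
    secondary: list[GenomicInterval] = field(default_factory=list)


@dataclass
class SineupDomains:
    """BD and ED of one candidate pair, in genomic and transcript coordinates.

    Transcript coordinates are 0-based half-open on the mature antisense
    transcript, 5'->3'.
    """

    bd_genomic: GenomicInterval
    bd_len_nt: int
    bd_tx_coords: tuple[int, int]
    ed_genomic: GenomicInterval
    ed_len_nt: int
    ed_tx_coords: tuple[int, int]
    ed_members: list[EmbeddedTE]
    ed_dist_to_3prime_nt: int


@dataclass
class MutantConstruct:
    """A designed construct sequence: wild type or a domain deletion."""

    name: str  # WT | dBD | dED
    sequence: str
    deleted_tx_interval: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def _tx_position(tx: TranscriptModel, genomic_pos: int) -> int:
    """Transcript coordinate of one exonic genomic base (5'->3')."""
    offset = 0
    if tx.strand == "+":
        for exon in tx.exons:
            if exon.start <= genomic_pos < exon.end:
                return offset + (genomic_pos - exon.start)
            offset += exon.length
    else:
        for exon in reversed(tx.exons):
            if exon.start <= genomic_pos < exon.end:
                return offset + (exon.end - 1 - genomic_pos)
            offset += exon.length
    raise DomainError(f"position {genomic_pos} is not exonic in {tx.transcript_id}")


def genomic_to_transcript_coords(
    tx: TranscriptModel, g: GenomicInterval
) -> tuple[int, int]:
    """Map a genomic interval onto mature-transcript coordinates.

    Only the exonic footprint of ``g`` is mapped; because ``g`` is
    genomically contiguous its footprint is always contiguous in the
    spliced transcript, so the result is a single (start, end) interval
    whose length equals the exonic overlap of ``g``. Raises for fully
    intronic input.
    """
    if g.chrom != tx.chrom:
        raise DomainError("interval on a different chromosome")
    runs = intersect_runs(
        [(iv.start, iv.end) for iv in tx.exons], [(g.start, g.end)]
    )
    if not runs:
        raise DomainError(
            f"interval [{g.start}, {g.end}) has no exonic overlap with "
            f"{tx.transcript_id}"
        )
    first_base, last_base = runs[0][0], runs[-1][1] - 1
    a = _tx_position(tx, first_base)
    b = _tx_position(tx, last_base)
    lo, hi = min(a, b), max(a, b)
    return lo, hi + 1


def transcript_to_genomic(
    tx: TranscriptModel, tx_interval: tuple[int, int]
) -> list[GenomicInterval]:
    """Inverse mapping: a transcript interval back to genomic exon pieces."""
    start, end = tx_interval
    if not (0 <= start < end <= tx.exonic_length):
        raise DomainError(f"transcript interval {tx_interval} out of range")
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    pieces: list[GenomicInterval] = []
    offset = 0
    for exon in exons:
        lo = max(start, offset)
        hi = min(end, offset + exon.length)
        if lo < hi:
            if tx.strand == "+":
                g_lo = exon.start + (lo - offset)
                g_hi = exon.start + (hi - offset)
            else:
                g_hi = exon.end - (lo - offset)
                g_lo = exon.end - (hi - offset)
            pieces.append(GenomicInterval(tx.chrom, g_lo, g_hi, tx.strand))
        offset += exon.length
    return sorted(pieces, key=lambda iv: iv.start)


# ---------------------------------------------------------------------------
# Domain computation
# ---------------------------------------------------------------------------

def compute_binding_domain(
    sense_tx: TranscriptModel, lnc_tx: TranscriptModel
) -> tuple[GenomicInterval, int]:
    """Locate the binding domain of an antisense/sense transcript pair.

    Returns the maximal contiguous exonic-intersection run containing at
    least one start-codon base, and its length. When a split codon touches
    several runs, the run covering most codon bases wins (leftmost on tie).
    """
    runs, _ = exonic_intersection(sense_tx, lnc_tx)
    codon = start_codon_intervals(sense_tx)
    best: tuple[int, GenomicInterval] | None = None
    for run in runs:
        covered = sum(run.intersection_nt(part) for part in codon)
        if covered >= 1 and (best is None or covered > best[0]):
            best = (covered, run)
    if best is None:
        raise DomainError(
            f"{lnc_tx.transcript_id}/{sense_tx.transcript_id}: "
            "not a TIS-overlapping pair"
        )
    return best[1], best[1].length


def compute_effector_domain(
    lnc_tx: TranscriptModel,
    tes: Sequence[EmbeddedTE],
    merge_gap_nt: int = 0,
) -> EffectorDomain:
    """Locate the effector domain from the embedded TE hits of a transcript.

    Hit footprints are clipped to exons and merged into clusters when they
    overlap or lie within ``merge_gap_nt`` of each other (default strict
    overlap/adjacency). The cluster nearest the transcript 3' end is the
    ED; others are reported as secondary. ``ed_len_nt`` is the exon-clipped
    union length and ``ed_dist_to_3prime_nt`` the gap between the ED's 3'
    edge and the transcript 3' end, in transcript coordinates.
    """
    if not tes:
        raise DomainError("no embedded TE hits given")
    exon_runs = [(iv.start, iv.end) for iv in lnc_tx.exons]
    # Cluster the raw hit intervals first (a hit straddling an intron stays
    # one unit), then clip each cluster's union to the exonic footprint.
    raw = [(te.hit.interval.start, te.hit.interval.end) for te in tes]
    padded = [(s, e + merge_gap_nt) for s, e in raw]
    clusters = [(s, e - merge_gap_nt) for s, e in merge_runs(padded)]

    annotated = []
    for s, e in clusters:
        member_runs = [
            (te.hit.interval.start, te.hit.interval.end)
            for te in tes
            if te.hit.interval.start < e and s < te.hit.interval.end
        ]
        clipped = intersect_runs(exon_runs, member_runs)
        if not clipped:
            continue  # intron-only cluster: no footprint in the mature RNA
        genomic = GenomicInterval(lnc_tx.chrom, s, e)
        tx_lo, tx_hi = genomic_to_transcript_coords(lnc_tx, genomic)
        length = sum(hi - lo for lo, hi in clipped)
        dist = lnc_tx.exonic_length - tx_hi
        annotated.append((dist, genomic, length))
    if not annotated:
        raise DomainError("TE hits have no exonic footprint")
    annotated.sort(key=lambda item: (item[0], item[1].start))
    dist, genomic, length = annotated[0]
    members = [
        te for te in tes
        if te.hit.interval.start < genomic.end and genomic.start < te.hit.interval.end
    ]
    return EffectorDomain(
        ed_genomic=genomic,
        ed_len_nt=length,
        ed_members=sorted(members, key=lambda te: te.hit.interval.start),
        ed_dist_to_3prime_nt=dist,
        secondary=[item[1] for item in annotated[1:]],
    )


def annotate_domains(
    sense_tx: TranscriptModel,
    lnc_tx: TranscriptModel,
    tes: Sequence[EmbeddedTE],
    merge_gap_nt: int = 0,
) -> SineupDomains:
    """Full BD + ED annotation of one candidate pair."""
    bd_genomic, bd_len = compute_binding_domain(sense_tx, lnc_tx)
    ed = compute_effector_domain(lnc_tx, tes, merge_gap_nt)
    return SineupDomains(
        bd_genomic=bd_genomic,
        bd_len_nt=bd_len,
        bd_tx_coords=genomic_to_transcript_coords(lnc_tx, bd_genomic),
        ed_genomic=ed.ed_genomic,
        ed_len_nt=ed.ed_len_nt,
        ed_tx_coords=genomic_to_transcript_coords(lnc_tx, ed.ed_genomic),
        ed_members=ed.ed_members,
        ed_dist_to_3prime_nt=ed.ed_dist_to_3prime_nt,
    )


# ---------------------------------------------------------------------------
# Mutant design
# ---------------------------------------------------------------------------

def make_deletion_mutant(
    wt_sequence: str, deleted: tuple[int, int], name: str = "mutant"
) -> MutantConstruct:
    """Delete a transcript-coordinate interval from the mature WT sequence."""
    start, end = deleted
    if not (0 <= start < end <= len(wt_sequence)):
        raise DomainError(
            f"deletion {deleted} out of range for a {len(wt_sequence)}-nt sequence"
        )
    return MutantConstruct(
        name=name,
        sequence=wt_sequence[:start] + wt_sequence[end:],
        deleted_tx_interval=(start, end),
    )


def design_constructs(
    lnc_tx: TranscriptModel,
    genome: Mapping,
    domains: SineupDomains,
) -> list[MutantConstruct]:
    """WT, dBD and dED construct sequences for one annotated candidate.

    Deletions are made in mature (spliced) transcript coordinates because
    the cloned construct is the mature RNA sequence.
    """
    wt_seq = spliced_sequence(lnc_tx, genome)
    wt = MutantConstruct(name="WT", sequence=wt_seq)
    dbd = make_deletion_mutant(wt_seq, domains.bd_tx_coords, name="dBD")
    ded = make_deletion_mutant(wt_seq, domains.ed_tx_coords, name="dED")
    return [wt, dbd, ded]
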