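"""RepeatMasker track parsing and embedded-TE calling within transcripts.

A SINEUP effector domain is an inverted SINE-derived sequence embedded in
the exons of the antisense transcript, so two things matter here beyond
plain parsing: whether a repeat hit is *exonic* in a given isoform (domains
act in the mature RNA; intron-only hits are discarded) and whether it is
*inverted*, i.e. its consensus strand is opposite to the transcript strand
(the genomic strand of the hit alone never defines inversion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation_io import GenomicInterval, TranscriptModel, intersect_runs

log = logging.getLogger("sineup_screen")

#: (repeat_class, repeat_family) pairs accepted as potential effector
#: domains: human SINE/Alu (incl. FLAM/FRAM monomers) and SINE/MIR, plus the
#: murine B2/B4 families carrying the canonical inverted SINEB2.
DEFAULT_TE_FAMILIES = frozenset({
    ("SINE", "Alu"), ("SINE", "MIR"), ("SINE", "B2"), ("SINE", "B4"),
})

_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "       repeat             position in repeat\n"
    "score   div. del. ins.  sequence  begin  end    (left)   repeat"
    "         class/family      begin  end    (left)   ID\n"
    "\n"
)


class RepeatParseError(ValueError):
    """Raised for malformed RepeatMasker records."""


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker annotation record (0-based half-open interval)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    repeat_family: str
    sw_score: float
    divergence_pct: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise RepeatParseError("repeat hit strand must be + or -")
        if not self.repeat_class or not self.repeat_family:
            raise RepeatParseError("repeat class/family must be non-empty")

    @property
    def class_family(self) -> tuple[str, str]:
        return (self.repeat_class, self.repeat_family)


@dataclass(frozen=True)
class EmbeddedTE:
    """A repeat hit placed within one transcript's mature structure."""

    hit: RepeatHit
    transcript_id: str
    exonic_overlap_nt: int
    exonic_fraction: float
    inverted: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.exonic_fraction <= 1.0):
            raise RepeatParseError("exonic_fraction outside [0, 1]")


def _split_class_family(token: str) -> tuple[str, str]:
    if "/" in token:
        cls, fam = token.split("/", 1)
    else:
        cls = fam = token
    return cls, fam


def parse_repeat_annotation(path, dialect: str = "out") -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file (or UCSC rmsk TSV) into hits.

    The standard ``.out`` layout is 3 header lines followed by
    whitespace-delimited records; the strand column uses ``+``/``C`` and
    positions are 1-based closed (converted here to 0-based half-open).
    ``dialect="rmsk"`` reads a headered UCSC rmsk-style TSV whose
    ``genoStart`` is already 0-based.
    """
    if dialect == "rmsk":
        return _parse_rmsk_tsv(path)
    if dialect != "out":
        raise ValueError(f"unknown repeat dialect {dialect!r}")

    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if lineno <= 3:
                continue
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 14:
                raise RepeatParseError(
                    f"truncated RepeatMasker record at line {lineno} "
                    f"({len(fields)} fields)"
                )
            try:
                sw_score = float(fields[0])
                divergence = float(fields[1])
                chrom = fields[4]
                begin, end = int(fields[5]), int(fields[6])
                strand_token = fields[8]
                name = fields[9]
                cls, fam = _split_class_family(fields[10])
            except ValueError as exc:
                raise RepeatParseError(
                    f"unparseable RepeatMasker record at line {lineno}: {exc}"
                ) from exc
            if strand_token not in ("+", "C"):
                raise RepeatParseError(
                    f"bad strand {strand_token!r} at line {lineno}"
                )
            strand = "+" if strand_token == "+" else "-"
            hits.append(RepeatHit(
                interval=GenomicInterval(chrom, begin - 1, end, strand),
                repeat_name=name,
                repeat_class=cls,
                repeat_family=fam,
                sw_score=sw_score,
                divergence_pct=divergence,
            ))
    return hits


def _parse_rmsk_tsv(path) -> list[RepeatHit]:
    hits: list[RepeatHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        needed = ("genoName", "genoStart", "genoEnd", "strand",
                  "repName", "repClass", "repFamily", "swScore", "milliDiv")
        for name in needed:
            if name not in col:
                raise RepeatParseError(f"rmsk TSV missing column {name}")
        for lineno, raw in enumerate(fh, start=2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise RepeatParseError(f"truncated rmsk record at line {lineno}")
            hits.append(RepeatHit(
                interval=GenomicInterval(
                    fields[col["genoName"]],
                    int(fields[col["genoStart"]]),
                    int(fields[col["genoEnd"]]),
                    fields[col["strand"]],
                ),
                repeat_name=fields[col["repName"]],
                repeat_class=fields[col["repClass"]],
                repeat_family=fields[col["repFamily"]],
                sw_score=float(fields[col["swScore"]]),
                divergence_pct=float(fields[col["milliDiv"]]) / 10.0,
            ))
    return hits


def write_repeat_annotation(hits: Iterable[RepeatHit], path) -> None:
    """Emit hits as a RepeatMasker ``.out`` file (1-based closed restored)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, hit in enumerate(hits, start=1):
            iv = hit.interval
            strand = "+" if iv.strand == "+" else "C"
            cls_fam = (
                hit.repeat_class if hit.repeat_class == hit.repeat_family
                else f"{hit.repeat_class}/{hit.repeat_family}"
            )
            fh.write(
                f"{hit.sw_score:7.0f} {hit.divergence_pct:5.1f}  0.0  0.0  "
                f"{iv.chrom}  {iv.start + 1}  {iv.end}  (0)  {strand}  "
                f"{hit.repeat_name}  {cls_fam}  1  {iv.length}  (0)  {i}\n"
            )


def exonic_te_hits(
    tx: TranscriptModel,
    hits: Sequence[RepeatHit],
    family_config: frozenset | set = DEFAULT_TE_FAMILIES,
    min_exonic_nt: int = 1,
) -> list[EmbeddedTE]:
    """Accepted-family repeat hits embedded in the mature transcript.

    Returns hits whose exonic overlap with ``tx`` is at least
    ``min_exonic_nt``, each carrying its inversion status relative to the
    *transcript* strand, sorted by genomic start. Hits on other chromosomes
    and intron-only hits are dropped.
    """
    if min_exonic_nt < 1:
        raise ValueError("min_exonic_nt must be >= 1")
    exon_runs = [(iv.start, iv.end) for iv in tx.exons]
    out: list[EmbeddedTE] = []
    for hit in hits:
        if hit.interval.chrom != tx.chrom:
            continue
        if hit.class_family not in family_config:
            continue
        overlap = sum(
            e - s for s, e in
            intersect_runs(exon_runs, [(hit.interval.start, hit.interval.end)])
        )
        if overlap < min_exonic_nt:
            continue
        out.append(EmbeddedTE(
            hit=hit,
            transcript_id=tx.transcript_id,
            exonic_overlap_nt=overlap,
            exonic_fraction=overlap / hit.interval.length,
            inverted=hit.interval.strand != tx.strand,
        ))
    return sorted(out, key=lambda te: (te.hit.interval.start, te.hit.repeat_name))
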