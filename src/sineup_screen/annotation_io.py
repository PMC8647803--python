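"""Strand-aware gene-annotation I/O and exon/CDS geometry.

Reads GENCODE-dialect GTF into transcript models with 0-based half-open
internal coordinates (GTF's 1-based closed convention is converted at the
I/O boundary and restored on re-emission), and provides the interval
geometry every downstream step of the SINEUP screen relies on: start-codon
localisation, strand-aware exonic intersection, and spliced sequence
extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

log = logging.getLogger("sineup_screen")

#: Biotype labels treated as lncRNA; spans GENCODE versions where the single
#: "lncRNA" label replaced the older "antisense"/"lincRNA" split.
DEFAULT_LNCRNA_BIOTYPES = frozenset({"lncRNA", "antisense", "lincRNA"})

#: Attribute keys searched for the gene biotype, in order.
BIOTYPE_KEYS = ("gene_type", "gene_biotype")

VALID_STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invalid geometry queries."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a strand (``.`` = unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_nt(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """One isoform: ordered exons plus optional CDS / start-codon features.

    All intervals share one chromosome and strand; exons are non-overlapping
    and sorted by genomic start regardless of strand (5'->3' order on the
    minus strand therefore runs right-to-left through ``exons``).
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    start_codon: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        self.start_codon = sorted(self.start_codon, key=lambda iv: iv.start)
        chroms = {iv.chrom for iv in self.exons}
        if len(chroms) != 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons on multiple chromosomes"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        sc_len = sum(iv.length for iv in self.start_codon)
        if sc_len not in (0, 3):
            raise AnnotationError(
                f"transcript {self.transcript_id}: start codon totals {sc_len} nt"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def exonic_length(self) -> int:
        return sum(iv.length for iv in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def is_coding(self) -> bool:
        return bool(self.cds) or bool(self.start_codon)


@dataclass
class GeneModel:
    """A gene: shared strand/biotype plus its isoforms and overall span."""

    gene_id: str
    gene_name: str
    biotype: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        # Coarse indexing only; overlap counting always works on exon sets.
        start = min(tx.span.start for tx in self.transcripts)
        end = max(tx.span.end for tx in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class AnnotationSet:
    """Genes indexed by id with a per-chromosome interval index over spans."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._index: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            span = gene.span
            tree = self._index.setdefault(span.chrom, IntervalTree())
            tree.addi(span.start, max(span.end, span.start + 1), gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def get(self, gene_id: str) -> GeneModel | None:
        return self.genes.get(gene_id)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span intersects [start, end) on chrom (coarse query)."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        ids = sorted({hit.data for hit in tree.overlap(start, end)})
        return [self.genes[g] for g in ids]

    def is_lncrna(self, gene_id: str, biotypes: frozenset[str] | set[str] = DEFAULT_LNCRNA_BIOTYPES) -> bool:
        return self.genes[gene_id].biotype in biotypes


# ---------------------------------------------------------------------------
# Interval set algebra (shared by screen and domains)
# ---------------------------------------------------------------------------

def merge_runs(runs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping/touching (start, end) runs into maximal runs."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(runs):
        if start >= end:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def intersect_runs(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Per-base intersection of two run lists, merged into maximal runs."""
    out: list[tuple[int, int]] = []
    for s1, e1 in merge_runs(a):
        for s2, e2 in merge_runs(b):
            lo, hi = max(s1, s2), min(e1, e2)
            if lo < hi:
                out.append((lo, hi))
    return merge_runs(out)


# ---------------------------------------------------------------------------
# GTF parsing / emission
# ---------------------------------------------------------------------------

def _first_attr(attrs, keys: Sequence[str]) -> str | None:
    for key in keys:
        if key in attrs:
            return attrs[key][0]
    return None


def parse_gene_annotation(
    path,
    biotype_config: frozenset[str] | set[str] = DEFAULT_LNCRNA_BIOTYPES,
    biotype_key: str | None = None,
) -> AnnotationSet:
    """Parse a GENCODE-dialect GTF file into an :class:`AnnotationSet`.

    Coordinates are converted from GTF's 1-based closed convention to
    0-based half-open. The gene biotype is read from ``gene_type`` or
    ``gene_biotype`` (or ``biotype_key`` when given); records without a
    biotype are skipped with a warning. ``biotype_config`` only controls
    which labels :meth:`AnnotationSet.is_lncrna` reports as lncRNA.
    """
    keys = (biotype_key,) if biotype_key else BIOTYPE_KEYS
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_cds: dict[str, list[GenomicInterval]] = {}
    tx_codon: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                start0, end0 = feat.start - 1, feat.end
                if start0 < 0 or end0 < start0:
                    raise ValueError("negative or inverted coordinates")
            except Exception as exc:
                raise AnnotationError(f"malformed GTF record at line {lineno}: {exc}") from exc

            attrs = feat.attributes
            gene_id = _first_attr(attrs, ("gene_id",))
            if gene_id is None:
                raise AnnotationError(f"malformed GTF record at line {lineno}: no gene_id")
            biotype = _first_attr(attrs, keys)
            gene_name = _first_attr(attrs, ("gene_name",)) or gene_id

            if feat.featuretype == "gene":
                gene_meta[gene_id] = {
                    "gene_name": gene_name, "biotype": biotype, "line": lineno,
                }
                continue

            tx_id = _first_attr(attrs, ("transcript_id",))
            if tx_id is None:
                continue  # gene-level or exotic feature; nothing to attach
            iv = GenomicInterval(feat.seqid, start0, end0, feat.strand)
            if feat.featuretype == "exon":
                tx_exons.setdefault(tx_id, []).append(iv)
            elif feat.featuretype == "CDS":
                tx_cds.setdefault(tx_id, []).append(iv)
            elif feat.featuretype == "start_codon":
                tx_codon.setdefault(tx_id, []).append(iv)
            elif feat.featuretype != "transcript":
                continue
            tx_meta.setdefault(tx_id, {
                "gene_id": gene_id, "gene_name": gene_name,
                "biotype": biotype, "strand": feat.strand, "line": lineno,
            })

    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, meta in tx_meta.items():
        if tx_id not in tx_exons:
            continue  # transcript line without exons: nothing to model
        gene_id = meta["gene_id"]
        biotype = gene_meta.get(gene_id, {}).get("biotype") or meta["biotype"]
        if biotype is None:
            log.warning(
                "skipping transcript %s (gene %s): no %s attribute",
                tx_id, gene_id, "/".join(keys),
            )
            continue
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            gene_name=gene_meta.get(gene_id, {}).get("gene_name") or meta["gene_name"],
            biotype=biotype,
            strand=meta["strand"],
            exons=tx_exons[tx_id],
            cds=tx_cds.get(tx_id, []),
            start_codon=tx_codon.get(tx_id, []),
        )
        genes.setdefault(gene_id, []).append(tx)

    models = []
    for gene_id, txs in genes.items():
        txs = sorted(txs, key=lambda t: t.transcript_id)
        strands = {t.strand for t in txs}
        if len(strands) != 1:
            raise AnnotationError(f"gene {gene_id}: transcripts on both strands")
        models.append(GeneModel(
            gene_id=gene_id,
            gene_name=txs[0].gene_name,
            biotype=txs[0].biotype,
            strand=txs[0].strand,
            transcripts=txs,
        ))
    return AnnotationSet(sorted(models, key=lambda g: g.gene_id))


def write_gtf(ann: AnnotationSet, path, source: str = "sineup_screen") -> None:
    """Re-emit an :class:`AnnotationSet` as GTF (1-based closed restored)."""

    def fmt(feature: str, iv: GenomicInterval, attrs: str) -> str:
        return (
            f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}"
        )

    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene_id in sorted(ann.genes):
            gene = ann.genes[gene_id]
            g_attr = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'gene_type "{gene.biotype}";'
            )
            fh.write(fmt("gene", gene.span, g_attr) + "\n")
            for tx in gene.transcripts:
                t_attr = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{gene.gene_name}"; gene_type "{gene.biotype}";'
                )
                fh.write(fmt("transcript", tx.span, t_attr) + "\n")
                for iv in tx.exons:
                    fh.write(fmt("exon", iv, t_attr) + "\n")
                for iv in tx.cds:
                    fh.write(fmt("CDS", iv, t_attr) + "\n")
                for iv in tx.start_codon:
                    fh.write(fmt("start_codon", iv, t_attr) + "\n")


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------

def start_codon_intervals(tx: TranscriptModel) -> list[GenomicInterval]:
    """Genomic interval(s) of the translation-initiation codon (3 nt total).

    Annotated ``start_codon`` features win; otherwise the codon is derived
    by walking 3 bases from the 5' end of the spliced CDS (which may split
    the codon across an intron). Raises for non-coding transcripts.
    """
    if tx.start_codon:
        return list(tx.start_codon)
    if not tx.cds:
        raise AnnotationError(f"non-coding transcript {tx.transcript_id}")
    pieces: list[GenomicInterval] = []
    remaining = 3
    cds = tx.cds if tx.strand == "+" else list(reversed(tx.cds))
    for iv in cds:
        if remaining == 0:
            break
        take = min(remaining, iv.length)
        if tx.strand == "+":
            pieces.append(GenomicInterval(iv.chrom, iv.start, iv.start + take, tx.strand))
        else:
            pieces.append(GenomicInterval(iv.chrom, iv.end - take, iv.end, tx.strand))
        remaining -= take
    if remaining:
        raise AnnotationError(
            f"transcript {tx.transcript_id}: CDS shorter than 3 nt"
        )
    return sorted(pieces, key=lambda iv: iv.start)


def exonic_intersection(
    txA: TranscriptModel, txB: TranscriptModel
) -> tuple[list[GenomicInterval], int]:
    """Per-base intersection of two exon sets, merged into maximal runs.

    Strand-agnostic and symmetric; returns ``([], 0)`` across chromosomes.
    """
    if txA.chrom != txB.chrom:
        return [], 0
    runs = intersect_runs(
        [(iv.start, iv.end) for iv in txA.exons],
        [(iv.start, iv.end) for iv in txB.exons],
    )
    intervals = [GenomicInterval(txA.chrom, s, e) for s, e in runs]
    return intervals, sum(e - s for s, e in runs)


def spliced_sequence(tx: TranscriptModel, genome: Mapping) -> str:
    """Mature (spliced) transcript sequence, 5'->3' in transcript orientation.

    ``genome`` is any chrom-keyed mapping whose values slice to sequence
    (a ``pyfaidx.Fasta`` or a plain dict of strings). Minus-strand output
    is reverse-complemented.
    """
    try:
        contig = genome[tx.chrom]
    except KeyError as exc:
        raise AnnotationError(f"contig {tx.chrom} missing from genome") from exc
    seq = "".join(str(contig[iv.start:iv.end]) for iv in tx.exons).upper()
    if len(seq) != tx.exonic_length:
        raise AnnotationError(
            f"transcript {tx.transcript_id}: exons exceed contig {tx.chrom} bounds"
        )
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
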