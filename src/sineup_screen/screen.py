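"""Four-stage structural screen for SINEUP-like antisense lncRNAs.

Starting from a differential-expression gene list, candidates are filtered
sequentially: (1) keep lncRNA-biotype genes; (2) keep genes with an exonic
(by default inverted) SINE of an accepted family; (3) keep genes whose
exons overlap a protein-coding gene on the opposite strand; (4) keep pairs
where the lncRNA's exons cover at least one base of the sense gene's start
codon. The stage order is fixed and per-stage survivor counts are part of
the report, so the funnel is directly comparable across runs.

The differential-expression requirement applies to the lncRNA only; the
sense gene's statistics (and any regulator-binding flags supplied with the
table) are reported as pass-through metadata, never filtered on. A gene
passes each structural stage if ANY isoform (pair) passes; the
best-supporting isoform pair is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotation_io import (
    DEFAULT_LNCRNA_BIOTYPES,
    AnnotationSet,
    GeneModel,
    TranscriptModel,
    exonic_intersection,
    start_codon_intervals,
)
from .repeats import DEFAULT_TE_FAMILIES, EmbeddedTE, RepeatHit, exonic_te_hits

log = logging.getLogger("sineup_screen")

STAGE_NAMES = ("lncrna", "embedded_te", "antisense_overlap", "tis_overlap")


@dataclass(frozen=True)
class DEGRecord:
    """One row of the input differential-expression table.

    ``fold_change`` is signed-linear: the sign is the direction and the
    magnitude the fold (-1.767 means 1.767-fold down). ``bound`` is
    optional pass-through metadata (e.g. whether the locus is bound by the
    perturbed regulator); it plays no role in filtering.
    """

    gene_id: str
    gene_name: str
    fold_change: float
    p_value: float
    direction: str  # up | down | noreg
    bound: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.gene_id}: p_value outside (0, 1]")
        if self.direction not in ("up", "down", "noreg"):
            raise ValueError(f"{self.gene_id}: bad direction {self.direction!r}")


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable policy of the screen; defaults match the published filter."""

    lncrna_biotypes: frozenset = DEFAULT_LNCRNA_BIOTYPES
    te_families: frozenset = DEFAULT_TE_FAMILIES
    require_inverted: bool = True
    minoverlap: int = 1
    min_exonic_nt: int = 1
    use_gene_spans: bool = False  # overlap on exon sets unless flipped

    def __post_init__(self) -> None:
        if self.minoverlap < 1:
            raise ValueError("minoverlap must be >= 1")
        if self.min_exonic_nt < 1:
            raise ValueError("min_exonic_nt must be >= 1")


@dataclass(frozen=True)
class AntisensePair:
    lnc_gene_id: str
    sense_gene_id: str
    overlap_nt: int
    lnc_transcript_id: str
    sense_transcript_id: str


@dataclass
class CandidatePair:
    """One screen output row: an antisense lncRNA / sense mRNA pair."""

    lnc_gene: GeneModel
    sense_gene: GeneModel
    lnc_deg: DEGRecord
    sense_deg: DEGRecord | None
    embedded_tes: list[EmbeddedTE]
    antisense_overlap_nt: int
    tis_overlap_nt: int
    supporting_isoform_pair: tuple[str, str]
    bound_flags: tuple[int | None, int | None] = (None, None)

    def validate(self, cfg: ScreenConfig) -> None:
        """Self-check the structural invariants every emitted row must hold."""
        if self.antisense_overlap_nt < 1:
            raise ValueError("candidate without antisense overlap")
        if not (1 <= self.tis_overlap_nt <= 3):
            raise ValueError("candidate TIS overlap outside 1..3 nt")
        if self.lnc_gene.strand == self.sense_gene.strand:
            raise ValueError("candidate genes on the same strand")
        ok = [
            te for te in self.embedded_tes
            if te.hit.class_family in cfg.te_families
            and (te.inverted or not cfg.require_inverted)
        ]
        if not ok:
            raise ValueError("candidate without accepted embedded TE")


@dataclass
class CandidateTable:
    """Screen result: candidate pairs plus per-stage funnel counts."""

    pairs: list[CandidatePair]
    stage_counts: dict[str, int]
    config: ScreenConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            sd = p.sense_deg
            rows.append({
                "lnc_gene_name": p.lnc_gene.gene_name,
                "lnc_gene_id": p.lnc_gene.gene_id,
                "lnc_fc": p.lnc_deg.fold_change,
                "lnc_p": p.lnc_deg.p_value,
                "lnc_direction": p.lnc_deg.direction,
                "lnc_bound": p.bound_flags[0],
                "sense_gene_name": p.sense_gene.gene_name,
                "sense_gene_id": p.sense_gene.gene_id,
                "sense_fc": sd.fold_change if sd else float("nan"),
                "sense_p": sd.p_value if sd else float("nan"),
                "sense_direction": sd.direction if sd else "noreg",
                "sense_bound": p.bound_flags[1],
                "antisense_overlap_nt": p.antisense_overlap_nt,
                "tis_overlap_nt": p.tis_overlap_nt,
                "n_embedded_te": len(p.embedded_tes),
                "lnc_transcript_id": p.supporting_isoform_pair[0],
                "sense_transcript_id": p.supporting_isoform_pair[1],
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DEG table loading
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "ensid", "ensembl_id", "ensembl_gene_id", "gene"),
    "gene_name": ("gene_name", "gene name", "symbol", "gene_symbol", "name"),
    "fold_change": ("fold_change", "fc", "foldchange", "log2fc", "log2foldchange", "logfc"),
    "p_value": ("p_value", "pvalue", "p", "pval", "p.value"),
    "direction": ("direction", "reg_direction", "reg. direction", "regulation"),
    "bound": ("bound", "bound_unbound", "bound/unbound"),
}


def load_deg_table(path, fc_scale: str = "linear") -> list[DEGRecord]:
    """Load a differential-expression table (TSV/CSV/xlsx) into records.

    Column names are matched case-insensitively against common aliases.
    ``fc_scale`` declares the fold-change convention of the file:
    ``"linear"`` for signed-linear values or ``"log2"`` for log2 fold
    changes (converted to signed-linear on load). A missing direction
    column is derived from the fold-change sign.
    """
    if fc_scale not in ("linear", "log2"):
        raise ValueError("fc_scale must be 'linear' or 'log2'")
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
    lower = {str(c).strip().lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for target, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[target] = lower[alias]
                break
    for required in ("gene_id", "fold_change", "p_value"):
        if required not in resolved:
            raise ValueError(f"DEG table {path}: no column for {required}")

    records: list[DEGRecord] = []
    for _, row in df.iterrows():
        fc = float(row[resolved["fold_change"]])
        if fc_scale == "log2":
            fc = 2.0 ** fc if fc >= 0 else -(2.0 ** -fc)
        if "direction" in resolved and isinstance(row[resolved["direction"]], str):
            direction = row[resolved["direction"]].strip().lower()
        else:
            direction = "up" if fc > 0 else "down"
        bound = None
        if "bound" in resolved and pd.notna(row[resolved["bound"]]):
            bound = int(row[resolved["bound"]])
        gene_id = str(row[resolved["gene_id"]]).strip()
        records.append(DEGRecord(
            gene_id=gene_id,
            gene_name=str(row[resolved["gene_name"]]).strip()
            if "gene_name" in resolved else gene_id,
            fold_change=fc,
            p_value=float(row[resolved["p_value"]]),
            direction=direction,
            bound=bound,
        ))
    return records


# ---------------------------------------------------------------------------
# Filter stages
# ---------------------------------------------------------------------------

def filter_lncrna(
    deg: Sequence[DEGRecord], ann: AnnotationSet, cfg: ScreenConfig
) -> list[str]:
    """Stage 1: DEG gene ids whose biotype is in the lncRNA set (input order)."""
    out: list[str] = []
    seen: set[str] = set()
    for rec in deg:
        if rec.gene_id in seen:
            continue
        seen.add(rec.gene_id)
        gene = ann.get(rec.gene_id)
        if gene is None:
            log.info("DEG gene %s not in annotation; dropped", rec.gene_id)
            continue
        if gene.biotype in cfg.lncrna_biotypes:
            out.append(rec.gene_id)
    return out


def _gene_embedded_tes(
    gene: GeneModel, hits: Sequence[RepeatHit], cfg: ScreenConfig
) -> dict[str, list[EmbeddedTE]]:
    """Accepted (and, if required, inverted) TEs per isoform of one gene."""
    per_tx: dict[str, list[EmbeddedTE]] = {}
    for tx in gene.transcripts:
        tes = exonic_te_hits(tx, hits, cfg.te_families, cfg.min_exonic_nt)
        if cfg.require_inverted:
            tes = [te for te in tes if te.inverted]
        if tes:
            per_tx[tx.transcript_id] = tes
    return per_tx


def filter_te(
    gene_ids: Sequence[str],
    ann: AnnotationSet,
    repeat_hits: Sequence[RepeatHit],
    cfg: ScreenConfig,
) -> list[str]:
    """Stage 2: genes with >=1 exonic accepted-family TE in some isoform."""
    by_chrom: dict[str, list[RepeatHit]] = {}
    for hit in repeat_hits:
        by_chrom.setdefault(hit.interval.chrom, []).append(hit)
    out = []
    for gene_id in gene_ids:
        gene = ann[gene_id]
        if _gene_embedded_tes(gene, by_chrom.get(gene.chrom, []), cfg):
            out.append(gene_id)
    return out


def _pair_overlap(
    lnc: GeneModel, sense: GeneModel, cfg: ScreenConfig
) -> tuple[int, str, str]:
    """Max exonic (or span) overlap over isoform pairs; returns best pair."""
    if cfg.use_gene_spans:
        nt = lnc.span.intersection_nt(sense.span)
        return nt, lnc.transcripts[0].transcript_id, sense.transcripts[0].transcript_id
    best = (0, "", "")
    for ltx in lnc.transcripts:
        for stx in sense.transcripts:
            _, nt = exonic_intersection(ltx, stx)
            if nt > best[0]:
                best = (nt, ltx.transcript_id, stx.transcript_id)
    return best


def filter_antisense(
    gene_ids: Sequence[str],
    ann: AnnotationSet,
    cfg: ScreenConfig,
) -> list[AntisensePair]:
    """Stage 3: lncRNA genes exon-overlapping an opposite-strand coding gene.

    Overlap is the per-base exonic intersection, maximised over isoform
    pairs; a pair is kept when it reaches ``cfg.minoverlap`` nt.
    """
    pairs: list[AntisensePair] = []
    for gene_id in gene_ids:
        lnc = ann[gene_id]
        span = lnc.span
        for other in ann.genes_overlapping(span.chrom, span.start, span.end):
            if other.gene_id == gene_id:
                continue
            if other.biotype != "protein_coding":
                continue
            if other.strand == lnc.strand:
                continue
            nt, ltx, stx = _pair_overlap(lnc, other, cfg)
            if nt >= cfg.minoverlap:
                pairs.append(AntisensePair(gene_id, other.gene_id, nt, ltx, stx))
    return pairs


def _tis_overlap_nt(lnc_tx: TranscriptModel, sense_tx: TranscriptModel) -> int:
    """Bases of the sense start codon covered by the lncRNA's exons (0..3)."""
    if not sense_tx.is_coding:
        return 0
    total = 0
    for codon_part in start_codon_intervals(sense_tx):
        for exon in lnc_tx.exons:
            total += exon.intersection_nt(codon_part)
    return total


def filter_tis_overlap(
    pairs: Sequence[AntisensePair], ann: AnnotationSet
) -> list[tuple[AntisensePair, int, tuple[str, str]]]:
    """Stage 4: pairs whose lncRNA exons cover >=1 nt of a sense start codon.

    Returns (pair, tis_overlap_nt, (lnc_tx, sense_tx)) with the overlap and
    supporting isoform pair maximised over isoform combinations.
    """
    kept = []
    for pair in pairs:
        lnc = ann[pair.lnc_gene_id]
        sense = ann[pair.sense_gene_id]
        coding = [tx for tx in sense.transcripts if tx.is_coding]
        if not coding:
            log.warning(
                "pair %s/%s dropped: sense gene has no coding isoform",
                pair.lnc_gene_id, pair.sense_gene_id,
            )
            continue
        best = (0, ("", ""))
        for stx in coding:
            for ltx in lnc.transcripts:
                nt = _tis_overlap_nt(ltx, stx)
                if nt > best[0]:
                    best = (nt, (ltx.transcript_id, stx.transcript_id))
        if best[0] >= 1:
            kept.append((pair, best[0], best[1]))
    return kept


def run_screen(
    deg: Sequence[DEGRecord],
    ann: AnnotationSet,
    repeat_hits: Sequence[RepeatHit],
    cfg: ScreenConfig | None = None,
) -> CandidateTable:
    """Run the full four-stage screen and assemble the candidate report.

    Output rows are one per (lncRNA gene, sense gene) pair, ordered
    lexicographically by (lnc gene_id, sense gene_id); every row is
    self-checked against the candidate invariants before being emitted.
    """
    cfg = cfg or ScreenConfig()
    deg_by_id = {}
    for rec in deg:
        deg_by_id.setdefault(rec.gene_id, rec)

    stage1 = filter_lncrna(deg, ann, cfg)
    stage2 = filter_te(stage1, ann, repeat_hits, cfg)
    stage3 = filter_antisense(stage2, ann, cfg)
    stage4 = filter_tis_overlap(stage3, ann)

    by_chrom: dict[str, list[RepeatHit]] = {}
    for hit in repeat_hits:
        by_chrom.setdefault(hit.interval.chrom, []).append(hit)

    pairs: list[CandidatePair] = []
    for pair, tis_nt, isoforms in stage4:
        lnc = ann[pair.lnc_gene_id]
        sense = ann[pair.sense_gene_id]
        per_tx = _gene_embedded_tes(lnc, by_chrom.get(lnc.chrom, []), cfg)
        tes = per_tx.get(isoforms[0]) or next(iter(per_tx.values()))
        lnc_deg = deg_by_id[pair.lnc_gene_id]
        sense_deg = deg_by_id.get(pair.sense_gene_id)
        cand = CandidatePair(
            lnc_gene=lnc,
            sense_gene=sense,
            lnc_deg=lnc_deg,
            sense_deg=sense_deg,
            embedded_tes=tes,
            antisense_overlap_nt=pair.overlap_nt,
            tis_overlap_nt=tis_nt,
            supporting_isoform_pair=isoforms,
            bound_flags=(lnc_deg.bound, sense_deg.bound if sense_deg else None),
        )
        cand.validate(cfg)
        pairs.append(cand)
    pairs.sort(key=lambda p: (p.lnc_gene.gene_id, p.sense_gene.gene_id))

    counts = {
        "deg_input": len({r.gene_id for r in deg}),
        "lncrna": len(stage1),
        "embedded_te": len(stage2),
        "antisense_overlap": len({(p.lnc_gene_id, p.sense_gene_id) for p in stage3}),
        "tis_overlap": len(pairs),
        "candidate_lnc_genes": len({p.lnc_gene.gene_id for p in pairs}),
    }
    return CandidateTable(pairs=pairs, stage_counts=counts, config=cfg)
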