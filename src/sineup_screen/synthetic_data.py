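"""Synthetic locus and expression generators for the SINEUP screen.

Real inputs to the screen are a genome-scale annotation, a RepeatMasker
track and a differential-expression table; none can ship with the package.
This module generates miniature replacements with the structural and
statistical properties the screen and the expression statistics assume:

* locus fixtures: antisense-lncRNA / sense-mRNA pairs with configurable
  TIS overlap and embedded SINEs of configurable family, orientation and
  exonic placement, planted alongside single-violation decoys (one decoy
  class per filter clause), written as GTF + RepeatMasker .out + DEG TSV
  + FASTA + a truth table;
* a five-pair fixture mirroring the published candidate table, including
  one locus with the canonical geometry (a 96-nt antisense block spanning
  the sense start codon and a FRAM monomer nested in an inverted Alu whose
  union is 222 nt near the transcript 3' end);
* bivariate log-scale expression matrices with a stated target Pearson
  correlation, and qPCR Cq tables whose 2^-ddCq analysis recovers planted
  fold changes in expectation.

Every fixture is deterministic for a fixed seed, and the locus generator
verifies its own contract before returning: each planted locus passes all
four screen predicates and each decoy passes every stage before, and fails
exactly at, its declared stage. Random sequence content is irrelevant to
the screen; the genome FASTA exists to exercise sequence extraction and
construct design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    write_gtf,
)
from .coexpression import CqTable, ExpressionMatrix
from .repeats import RepeatHit, write_repeat_annotation
from .screen import (
    DEGRecord,
    ScreenConfig,
    filter_antisense,
    filter_te,
    filter_tis_overlap,
)

VIOLATIONS = (
    "not_lncRNA", "not_DEG_lnc", "no_accepted_TE", "TE_not_inverted",
    "TE_intronic", "same_strand_overlap", "no_overlap", "no_TIS_overlap",
)

#: Screen stage at which each decoy class must fail.
VIOLATION_STAGE = {
    "not_lncRNA": "lncrna",
    "not_DEG_lnc": "lncrna",
    "no_accepted_TE": "embedded_te",
    "TE_not_inverted": "embedded_te",
    "TE_intronic": "embedded_te",
    "same_strand_overlap": "antisense_overlap",
    "no_overlap": "antisense_overlap",
    "no_TIS_overlap": "tis_overlap",
}

_STAGE_ORDER = ("lncrna", "embedded_te", "antisense_overlap", "tis_overlap")

_FAMILY_NAMES = {
    ("SINE", "Alu"): "AluY",
    ("SINE", "MIR"): "MIRb",
    ("SINE", "B2"): "B2_Mm1a",
    ("SINE", "B4"): "B4A",
}

_LOCUS_STRIDE = 6000


class FixtureError(ValueError):
    """Raised when a locus spec is impossible or self-verification fails."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    """Descriptor of one planted SINEUP-like locus."""

    lnc_name: str
    lnc_id: str
    sense_name: str
    sense_id: str
    lnc_fc: float
    lnc_p: float
    lnc_direction: str
    sense_fc: float
    sense_p: float
    sense_direction: str
    lnc_bound: int = 0
    sense_bound: int = 0
    lnc_biotype: str = "lncRNA"
    te_family: tuple[str, str] = ("SINE", "Alu")
    tis_overlap_nt: int = 3
    bd_exon_len: int = 96  # 5' lncRNA exon length = antisense-block length
    nested_te: bool = False  # FRAM-in-Alu dimeric configuration


@dataclass(frozen=True)
class Decoy:
    """Descriptor of one single-violation decoy locus."""

    violation: str
    index: int

    def __post_init__(self) -> None:
        if self.violation not in VIOLATIONS:
            raise FixtureError(f"unknown violation {self.violation!r}")


@dataclass
class LocusSpec:
    planted: list[PlantedPair] = field(default_factory=list)
    decoys: list[Decoy] = field(default_factory=list)
    contig: str = "chrS"
    contig_length: int | None = None  # auto-sized when None
    seed: int = 0


@dataclass(frozen=True)
class ExprSpec:
    """Bivariate log-scale expression with a target Pearson correlation."""

    n_samples: int
    target_pearson: float
    seed: int = 0
    gene_x: str = "CHD8"
    gene_y: str = "RAB11B-AS1"
    mean_x: float = 6.0
    mean_y: float = 4.0
    sd_x: float = 1.0
    sd_y: float = 1.0
    unit: str = "logCPM"
    group_sizes: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if abs(self.target_pearson) > 1:
            raise FixtureError("|target_pearson| must be <= 1")
        if self.n_samples < 3:
            raise FixtureError("n_samples must be >= 3")


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def _sense_gene(
    offset: int, contig: str, gene_id: str, gene_name: str
) -> GeneModel:
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        gene_name=gene_name,
        biotype="protein_coding",
        strand="+",
        exons=[GenomicInterval(contig, offset + 1000, offset + 1600, "+")],
        cds=[GenomicInterval(contig, offset + 1200, offset + 1500, "+")],
        start_codon=[GenomicInterval(contig, offset + 1200, offset + 1203, "+")],
    )
    return GeneModel(gene_id, gene_name, "protein_coding", "+", [tx])


def _lnc_gene(
    offset: int,
    contig: str,
    gene_id: str,
    gene_name: str,
    biotype: str,
    strand: str,
    tis_overlap_nt: int,
    bd_exon_len: int,
    bd_mode: str,  # tis | utr3 | none
) -> GeneModel:
    if not (1 <= tis_overlap_nt <= 3):
        raise FixtureError(f"TIS overlap must be 1..3 nt, got {tis_overlap_nt}")
    if bd_exon_len < tis_overlap_nt:
        raise FixtureError("bd_exon_len shorter than requested TIS overlap")
    te_exon = GenomicInterval(contig, offset + 200, offset + 500, strand)
    if bd_mode == "tis":
        end = offset + 1200 + tis_overlap_nt
        bd_exon = GenomicInterval(contig, end - bd_exon_len, end, strand)
    elif bd_mode == "utr3":
        bd_exon = GenomicInterval(contig, offset + 1520, offset + 1590, strand)
    elif bd_mode == "none":
        bd_exon = GenomicInterval(contig, offset + 1700, offset + 1790, strand)
    else:  # pragma: no cover - internal
        raise FixtureError(f"unknown bd_mode {bd_mode!r}")
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        gene_name=gene_name,
        biotype=biotype,
        strand=strand,
        exons=[te_exon, bd_exon],
    )
    return GeneModel(gene_id, gene_name, biotype, strand, [tx])


def _te_hits(
    offset: int,
    contig: str,
    lnc_strand: str,
    family: tuple[str, str],
    inverted: bool,
    placement: str,  # exonic | intronic
    nested: bool,
    rng: np.random.Generator,
) -> list[RepeatHit]:
    strand = ("-" if lnc_strand == "+" else "+") if inverted else lnc_strand

    def hit(start: int, end: int, name: str, fam: tuple[str, str]) -> RepeatHit:
        return RepeatHit(
            interval=GenomicInterval(contig, start, end, strand),
            repeat_name=name,
            repeat_class=fam[0],
            repeat_family=fam[1],
            sw_score=float(rng.integers(300, 3000)),
            divergence_pct=round(float(rng.uniform(5, 25)), 1),
        )

    if placement == "intronic":
        return [hit(offset + 600, offset + 830,
                    _FAMILY_NAMES.get(family, family[1]), family)]
    if nested:
        # Dimeric configuration: a free right Alu monomer nested inside a
        # full-length inverted Alu; the union spans 222 nt.
        return [
            hit(offset + 240, offset + 462, "AluY", ("SINE", "Alu")),
            hit(offset + 280, offset + 420, "FRAM", ("SINE", "Alu")),
        ]
    return [hit(offset + 250, offset + 480,
                _FAMILY_NAMES.get(family, family[1]), family)]


def _decoy_geometry(violation: str) -> dict:
    geometry = {
        "biotype": "lncRNA", "in_deg": True, "family": ("SINE", "Alu"),
        "inverted": True, "placement": "exonic", "strand": "-",
        "bd_mode": "tis",
    }
    if violation == "not_lncRNA":
        geometry["biotype"] = "protein_coding"
    elif violation == "not_DEG_lnc":
        geometry["in_deg"] = False
    elif violation == "no_accepted_TE":
        geometry["family"] = ("LINE", "L1")
    elif violation == "TE_not_inverted":
        geometry["inverted"] = False
    elif violation == "TE_intronic":
        geometry["placement"] = "intronic"
    elif violation == "same_strand_overlap":
        geometry["strand"] = "+"
    elif violation == "no_overlap":
        geometry["bd_mode"] = "none"
    elif violation == "no_TIS_overlap":
        geometry["bd_mode"] = "utr3"
    return geometry


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class ScreenFixture:
    """In-memory fixture plus writers for the on-disk file set."""

    annotation: AnnotationSet
    repeat_hits: list[RepeatHit]
    deg: list[DEGRecord]
    genome: dict[str, str]
    truth: pd.DataFrame
    spec: LocusSpec

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out / "annotation.gtf",
            "rmsk": out / "repeats.out",
            "deg": out / "deg.tsv",
            "genome": out / "genome.fa",
            "truth": out / "truth.tsv",
        }
        write_gtf(self.annotation, paths["gtf"])
        write_repeat_annotation(self.repeat_hits, paths["rmsk"])
        deg_df = pd.DataFrame([{
            "gene_id": r.gene_id, "gene_name": r.gene_name,
            "fold_change": f"{r.fold_change:.5f}", "p_value": f"{r.p_value:.5g}",
            "direction": r.direction,
            "bound": "" if r.bound is None else r.bound,
        } for r in self.deg])
        deg_df.to_csv(paths["deg"], sep="\t", index=False)
        with open(paths["genome"], "w") as fh:
            for contig in sorted(self.genome):
                fh.write(f">{contig}\n")
                seq = self.genome[contig]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_screen_fixture(
    spec: LocusSpec, verify_config: ScreenConfig | None = None
) -> ScreenFixture:
    """Build a screen fixture from a locus spec (deterministic per seed).

    Loci are laid out in disjoint windows on one contig: planted pairs
    first, decoys after, one sense/antisense pair per window. The truth
    table records each locus and, for decoys, the violated criterion. The
    generated fixture is verified against the screen predicates before
    being returned.
    """
    rng = np.random.default_rng(spec.seed)
    n_loci = len(spec.planted) + len(spec.decoys)
    needed = n_loci * _LOCUS_STRIDE + 2000
    length = spec.contig_length if spec.contig_length is not None else needed
    if length < needed:
        raise FixtureError(
            f"contig length {length} too short for {n_loci} loci (need {needed})"
        )

    genes: list[GeneModel] = []
    hits: list[RepeatHit] = []
    deg: list[DEGRecord] = []
    truth_rows: list[dict] = []

    for i, pp in enumerate(spec.planted):
        offset = i * _LOCUS_STRIDE
        genes.append(_sense_gene(offset, spec.contig, pp.sense_id, pp.sense_name))
        genes.append(_lnc_gene(
            offset, spec.contig, pp.lnc_id, pp.lnc_name, pp.lnc_biotype, "-",
            pp.tis_overlap_nt, pp.bd_exon_len, "tis",
        ))
        hits.extend(_te_hits(
            offset, spec.contig, "-", pp.te_family, inverted=True,
            placement="exonic", nested=pp.nested_te, rng=rng,
        ))
        deg.append(DEGRecord(pp.lnc_id, pp.lnc_name, pp.lnc_fc, pp.lnc_p,
                             pp.lnc_direction, pp.lnc_bound))
        deg.append(DEGRecord(pp.sense_id, pp.sense_name, pp.sense_fc, pp.sense_p,
                             pp.sense_direction, pp.sense_bound))
        truth_rows.append({
            "locus": f"planted_{i:02d}", "lnc_gene_id": pp.lnc_id,
            "lnc_gene_name": pp.lnc_name, "sense_gene_id": pp.sense_id,
            "status": "planted", "violation": "",
        })

    for j, decoy in enumerate(spec.decoys):
        offset = (len(spec.planted) + j) * _LOCUS_STRIDE
        geometry = _decoy_geometry(decoy.violation)
        lnc_id = f"DLNC{decoy.index:04d}"
        sense_id = f"DSEN{decoy.index:04d}"
        genes.append(_sense_gene(offset, spec.contig, sense_id, sense_id))
        genes.append(_lnc_gene(
            offset, spec.contig, lnc_id, lnc_id, geometry["biotype"],
            geometry["strand"], 3, 96, geometry["bd_mode"],
        ))
        hits.extend(_te_hits(
            offset, spec.contig, geometry["strand"], geometry["family"],
            geometry["inverted"], geometry["placement"], nested=False, rng=rng,
        ))
        if geometry["in_deg"]:
            fc = float(rng.uniform(1.5, 3.0)) * (1 if rng.random() < 0.5 else -1)
            deg.append(DEGRecord(
                lnc_id, lnc_id, round(fc, 5),
                round(float(rng.uniform(1e-4, 0.04)), 5),
                "up" if fc > 0 else "down", 0,
            ))
        sense_fc = float(rng.uniform(1.0, 1.3)) * (1 if rng.random() < 0.5 else -1)
        deg.append(DEGRecord(
            sense_id, sense_id, round(sense_fc, 5),
            round(float(rng.uniform(0.1, 0.9)), 5), "noreg", 0,
        ))
        truth_rows.append({
            "locus": f"decoy_{j:02d}", "lnc_gene_id": lnc_id,
            "lnc_gene_name": lnc_id, "sense_gene_id": sense_id,
            "status": "decoy", "violation": decoy.violation,
        })

    fixture = ScreenFixture(
        annotation=AnnotationSet(sorted(genes, key=lambda g: g.gene_id)),
        repeat_hits=hits,
        deg=deg,
        genome={spec.contig: _random_genome(rng, length)},
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )
    verify_fixture(fixture, verify_config or ScreenConfig())
    return fixture


def _locus_stage_results(
    fixture: ScreenFixture, lnc_id: str, sense_id: str, cfg: ScreenConfig
) -> dict[str, bool]:
    ann = fixture.annotation
    deg_ids = {r.gene_id for r in fixture.deg}
    results = {}
    results["lncrna"] = (
        lnc_id in deg_ids and ann[lnc_id].biotype in cfg.lncrna_biotypes
    )
    results["embedded_te"] = bool(
        filter_te([lnc_id], ann, fixture.repeat_hits, cfg)
    )
    pairs = [
        p for p in filter_antisense([lnc_id], ann, cfg)
        if p.sense_gene_id == sense_id
    ]
    results["antisense_overlap"] = bool(pairs)
    results["tis_overlap"] = bool(filter_tis_overlap(pairs, ann))
    return results


def verify_fixture(fixture: ScreenFixture, cfg: ScreenConfig) -> None:
    """Assert the generator contract against the public screen predicates.

    Planted loci must pass all four stages; each decoy must pass every
    stage before its declared one and fail at exactly that stage.
    """
    for row in fixture.truth.itertuples():
        stages = _locus_stage_results(
            fixture, row.lnc_gene_id, row.sense_gene_id, cfg
        )
        if row.status == "planted":
            failed = [s for s in _STAGE_ORDER if not stages[s]]
            if failed:
                raise FixtureError(
                    f"planted locus {row.lnc_gene_id} fails stage(s) {failed}"
                )
            continue
        expected = VIOLATION_STAGE[row.violation]
        for stage in _STAGE_ORDER:
            if stage == expected:
                if stages[stage]:
                    raise FixtureError(
                        f"decoy {row.lnc_gene_id} ({row.violation}) "
                        f"unexpectedly passes stage {stage}"
                    )
                break
            if not stages[stage]:
                raise FixtureError(
                    f"decoy {row.lnc_gene_id} ({row.violation}) "
                    f"fails early at stage {stage}"
                )


# ---------------------------------------------------------------------------
# Published-candidate-table fixture
# ---------------------------------------------------------------------------

#: The five reported candidate pairs: (lnc name, lnc id, FC, p, direction,
#: bound, sense name, sense id, FC, p, direction, bound).
REPORTED_CANDIDATE_PAIRS = (
    ("RP11-400F19.6", "ENSG00000266962", 2.03495, 0.00009, "up", 0,
     "HSD17B1", "ENSG00000108786", 1.29275, 0.60422, "noreg", 0),
    ("RP11-115C21.2", "ENSG00000246089", 1.89649, 0.00336, "up", 0,
     "MCPH1", "ENSG00000147316", 1.12372, 0.48333, "noreg", 1),
    ("RAB11B-AS1", "ENSG00000269386", 1.84850, 0.00519, "up", 0,
     "RAB11B", "ENSG00000185236", 1.46253, 0.02023, "up", 1),
    ("ST7-AS1", "ENSG00000227199", -1.76710, 0.00991, "down", 0,
     "ST7", "ENSG00000004866", 1.06260, 0.71902, "noreg", 1),
    ("CTD-2517M22.14", "ENSG00000255182", 2.60614, 0.02712, "up", 0,
     "PPP1R16A", "ENSG00000160972", 2.17035, 0.00004, "up", 0),
)

#: TE family planted per pair; the RAB11B-AS1 locus gets the nested
#: FRAM-in-Alu configuration, the others alternate Alu and MIR.
_REPORTED_FAMILIES = (
    ("SINE", "Alu"), ("SINE", "MIR"), ("SINE", "Alu"),
    ("SINE", "MIR"), ("SINE", "Alu"),
)


def reported_candidates_spec(n_decoys: int = 30, seed: int = 7) -> LocusSpec:
    """Locus spec mirroring the five published candidate pairs plus decoys.

    Planted fold changes and p-values are the published ones; the
    RAB11B-AS1-like locus carries the canonical geometry (96-nt antisense
    block over the TIS; nested FRAM/Alu with a 222-nt union). Decoys cycle
    through the eight single-violation classes.
    """
    planted = []
    for i, row in enumerate(REPORTED_CANDIDATE_PAIRS):
        planted.append(PlantedPair(
            lnc_name=row[0], lnc_id=row[1], lnc_fc=row[2], lnc_p=row[3],
            lnc_direction=row[4], lnc_bound=row[5],
            sense_name=row[6], sense_id=row[7], sense_fc=row[8],
            sense_p=row[9], sense_direction=row[10], sense_bound=row[11],
            te_family=_REPORTED_FAMILIES[i],
            nested_te=(row[0] == "RAB11B-AS1"),
        ))
    decoys = [
        Decoy(violation=VIOLATIONS[k % len(VIOLATIONS)], index=k)
        for k in range(n_decoys)
    ]
    return LocusSpec(planted=planted, decoys=decoys, seed=seed)


# ---------------------------------------------------------------------------
# Expression and qPCR generators
# ---------------------------------------------------------------------------

def generate_correlated_expression(spec: ExprSpec) -> ExpressionMatrix:
    """Two gene rows from a bivariate normal with the target correlation.

    Values are drawn on the log scale (logCPM-like); for ``rho = +/-1``
    the second gene is an exact affine image of the first.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.target_pearson
    zx = rng.standard_normal(spec.n_samples)
    zy = rng.standard_normal(spec.n_samples)
    x = spec.mean_x + spec.sd_x * zx
    y = spec.mean_y + spec.sd_y * (rho * zx + np.sqrt(1.0 - rho * rho) * zy)
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    values = pd.DataFrame(
        [x, y], index=[spec.gene_x, spec.gene_y], columns=samples
    )
    groups = None
    if spec.group_sizes is not None:
        if sum(n for _, n in spec.group_sizes) != spec.n_samples:
            raise FixtureError("group sizes must sum to n_samples")
        labels = [lab for lab, n in spec.group_sizes for _ in range(n)]
        groups = pd.Series(labels, index=samples)
    return ExpressionMatrix(values=values, unit=spec.unit, sample_groups=groups)


def generate_cq_table(
    n_samples: int,
    n_replicates: int,
    true_fold_changes: dict[str, float],
    noise_sd: float,
    seed: int = 0,
    reference_gene: str = "NONO",
    calibrator_sample: str = "control",
) -> CqTable:
    """Cq table whose 2^-ddCq analysis recovers the planted fold changes.

    ``n_samples`` counts the calibrator plus the perturbed samples; each
    perturbed sample carries the same planted fold change per target gene
    (signed-linear input; negative values mean down-regulation and are
    converted to a ratio). Cq construction: the planted effect shifts the
    target Cq by -log2(ratio); Gaussian cycle noise of ``noise_sd`` is
    added independently to every replicate well.
    """
    if noise_sd < 0:
        raise FixtureError("noise_sd must be >= 0")
    if n_samples < 2:
        raise FixtureError("need the calibrator plus >=1 perturbed sample")
    rng = np.random.default_rng(seed)
    samples = [calibrator_sample] + [f"treated_{i + 1}" for i in range(n_samples - 1)]
    base_cq = {reference_gene: 20.0}
    for k, gene in enumerate(sorted(true_fold_changes)):
        base_cq[gene] = 24.0 + 0.5 * k

    rows = []
    for sample in samples:
        for gene, base in base_cq.items():
            shift = 0.0
            if gene != reference_gene and sample != calibrator_sample:
                fc = true_fold_changes[gene]
                ratio = fc if fc > 0 else 1.0 / -fc
                shift = -np.log2(ratio)
            for rep in range(n_replicates):
                rows.append({
                    "sample": sample, "gene": gene, "replicate": rep + 1,
                    "cq": base + shift + noise_sd * rng.standard_normal(),
                })
    return CqTable(
        data=pd.DataFrame(rows),
        reference_gene=reference_gene,
        calibrator_sample=calibrator_sample,
    )
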