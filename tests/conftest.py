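"""Shared builders and independent brute-force oracles.

The oracles work on explicit per-base sets and never call the interval
algebra they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from sineup_screen.annotation_io import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from sineup_screen.synthetic_data import (
    VIOLATIONS,
    Decoy,
    LocusSpec,
    PlantedPair,
)

# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def make_tx(
    exons,
    strand="+",
    chrom="chr1",
    tx_id="T1",
    gene_id="G1",
    biotype="lncRNA",
    cds=(),
    start_codon=(),
):
    """Build a TranscriptModel from bare (start, end) tuples."""
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        gene_name=gene_id,
        biotype=biotype,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds],
        start_codon=[GenomicInterval(chrom, s, e, strand) for s, e in start_codon],
    )


def make_gene(tx, biotype=None):
    return GeneModel(
        gene_id=tx.gene_id,
        gene_name=tx.gene_name,
        biotype=biotype or tx.biotype,
        strand=tx.strand,
        transcripts=[tx],
    )


# ---------------------------------------------------------------------------
# Per-base oracles
# ---------------------------------------------------------------------------

def base_set(intervals):
    """Explicit set of genomic base positions covered by (start, end) runs."""
    out = set()
    for iv in intervals:
        s, e = (iv.start, iv.end) if hasattr(iv, "start") else iv
        out |= set(range(s, e))
    return out


def runs_from_bases(bases):
    """Maximal sorted runs from an explicit base set."""
    runs = []
    for b in sorted(bases):
        if runs and b == runs[-1][1]:
            runs[-1][1] = b + 1
        else:
            runs.append([b, b + 1])
    return [tuple(r) for r in runs]


def oracle_candidates(fixture, cfg):
    """Brute-force screen oracle: per-base predicate over all triples.

    Evaluates all (lnc isoform x sense isoform x TE hit) combinations on
    explicit base sets; only uses annotated start_codon features. Returns
    the set of candidate (lnc_gene_id, sense_gene_id) pairs.
    """
    ann = fixture.annotation
    deg_ids = {r.gene_id for r in fixture.deg}
    pairs = set()
    for lnc in ann.genes.values():
        if lnc.gene_id not in deg_ids or lnc.biotype not in cfg.lncrna_biotypes:
            continue
        te_ok = False
        for ltx in lnc.transcripts:
            exon_bases = base_set(ltx.exons)
            for hit in fixture.repeat_hits:
                if hit.interval.chrom != ltx.chrom:
                    continue
                if (hit.repeat_class, hit.repeat_family) not in cfg.te_families:
                    continue
                if cfg.require_inverted and hit.interval.strand == ltx.strand:
                    continue
                overlap = len(exon_bases & base_set([hit.interval]))
                if overlap >= cfg.min_exonic_nt:
                    te_ok = True
        if not te_ok:
            continue
        for sense in ann.genes.values():
            if sense.biotype != "protein_coding" or sense.strand == lnc.strand:
                continue
            if sense.chrom != lnc.chrom:
                continue
            as_ok = any(
                len(base_set(ltx.exons) & base_set(stx.exons)) >= cfg.minoverlap
                for ltx in lnc.transcripts
                for stx in sense.transcripts
            )
            tis_ok = any(
                len(base_set(ltx.exons) & base_set(stx.start_codon)) >= 1
                for ltx in lnc.transcripts
                for stx in sense.transcripts
                if stx.start_codon
            )
            if as_ok and tis_ok:
                pairs.add((lnc.gene_id, sense.gene_id))
    return pairs


def oracle_binding_domain(sense_tx, lnc_tx):
    """BD oracle: connected run of the per-base exon intersection that
    contains a start-codon base (max codon coverage, leftmost tie)."""
    inter = base_set(sense_tx.exons) & base_set(lnc_tx.exons)
    codon = base_set(sense_tx.start_codon)
    best = None
    for s, e in runs_from_bases(inter):
        covered = len(set(range(s, e)) & codon)
        if covered >= 1 and (best is None or covered > best[0]):
            best = (covered, s, e)
    return None if best is None else (best[1], best[2])


def oracle_ols(x, y):
    """Closed-form normal-equation OLS with the t-statistic slope p-value."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    syy = ((y - ym) ** 2).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    r = sxy / np.sqrt(sxx * syy)
    resid = y - (intercept + slope * x)
    se = np.sqrt((resid ** 2).sum() / (n - 2) / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, r, p


# ---------------------------------------------------------------------------
# Randomised fixture specs
# ---------------------------------------------------------------------------

def random_locus_spec(rng: np.random.Generator, n_planted: int, n_decoys: int,
                      seed: int) -> LocusSpec:
    """A randomised locus spec with varied planted geometry."""
    planted = []
    for i in range(n_planted):
        fc = float(rng.uniform(1.5, 3.0)) * (1 if rng.random() < 0.5 else -1)
        planted.append(PlantedPair(
            lnc_name=f"LNC{i}", lnc_id=f"PLNC{seed:04d}{i:02d}",
            sense_name=f"SEN{i}", sense_id=f"PSEN{seed:04d}{i:02d}",
            lnc_fc=round(fc, 4), lnc_p=round(float(rng.uniform(1e-4, 0.04)), 5),
            lnc_direction="up" if fc > 0 else "down",
            sense_fc=1.1, sense_p=0.5, sense_direction="noreg",
            te_family=("SINE", "Alu") if rng.random() < 0.5 else ("SINE", "MIR"),
            tis_overlap_nt=int(rng.integers(1, 4)),
            bd_exon_len=int(rng.integers(50, 150)),
            nested_te=bool(rng.random() < 0.3),
        ))
    decoys = [
        Decoy(violation=VIOLATIONS[int(rng.integers(len(VIOLATIONS)))], index=k)
        for k in range(n_decoys)
    ]
    return LocusSpec(planted=planted, decoys=decoys, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
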