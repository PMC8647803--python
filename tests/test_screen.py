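"""The four-stage candidate filter and its report."""

import numpy as np
import pytest

from sineup_screen.annotation_io import AnnotationSet
from sineup_screen.screen import (
    DEGRecord,
    ScreenConfig,
    filter_antisense,
    filter_lncrna,
    filter_te,
    filter_tis_overlap,
    load_deg_table,
    run_screen,
)
from sineup_screen.synthetic_data import (
    Decoy,
    LocusSpec,
    generate_screen_fixture,
    reported_candidates_spec,
)

from conftest import make_gene, make_tx

from sineup_screen.repeats import RepeatHit
from sineup_screen.annotation_io import GenomicInterval


def deg(gene_id, fc=2.0, p=0.01, direction="up"):
    return DEGRecord(gene_id, gene_id, fc, p, direction)


def alu(start, end, strand="+", chrom="chr1"):
    return RepeatHit(GenomicInterval(chrom, start, end, strand),
                     "AluY", "SINE", "Alu", 1000.0, 12.0)


@pytest.fixture
def cfg():
    return ScreenConfig()


class TestFilterLncrna:
    def test_empty_deg(self, cfg):
        ann = AnnotationSet([])
        assert filter_lncrna([], ann, cfg) == []

    def test_biotype_subset(self, cfg):
        ann = AnnotationSet([
            make_gene(make_tx([(0, 100)], gene_id="L", tx_id="L.t")),
            make_gene(make_tx([(200, 300)], gene_id="P", tx_id="P.t",
                              biotype="protein_coding")),
        ])
        assert filter_lncrna([deg("L"), deg("P")], ann, cfg) == ["L"]

    def test_order_preserved_and_unresolvable_dropped(self, cfg):
        genes = [make_gene(make_tx([(i * 200, i * 200 + 100)],
                                   gene_id=f"G{i}", tx_id=f"G{i}.t",
                                   biotype="lncRNA" if i % 3 else "protein_coding"))
                 for i in range(10)]
        ann = AnnotationSet(genes)
        records = [deg(f"G{i}") for i in (7, 2, 5, 0, 1, 4, 6, 9)] + [deg("MISSING")]
        # lncRNA-biotype ids among the queried (i % 3 != 0), in input order
        assert filter_lncrna(records, ann, cfg) == ["G7", "G2", "G5", "G1", "G4"]


class TestFilterTe:
    def test_exonic_inverted_alu_retained(self, cfg):
        gene = make_gene(make_tx([(0, 500)], strand="-", gene_id="L", tx_id="L.t"))
        ann = AnnotationSet([gene])
        assert filter_te(["L"], ann, [alu(100, 300, "+")], cfg) == ["L"]

    def test_intronic_only_alu_dropped(self, cfg):
        gene = make_gene(make_tx([(0, 100), (400, 500)], strand="-",
                                 gene_id="L", tx_id="L.t"))
        ann = AnnotationSet([gene])
        assert filter_te(["L"], ann, [alu(150, 350, "+")], cfg) == []

    def test_inversion_requirement_config_switch(self):
        gene = make_gene(make_tx([(0, 500)], strand="+", gene_id="L", tx_id="L.t"))
        ann = AnnotationSet([gene])
        same_orientation_mir = RepeatHit(
            GenomicInterval("chr1", 100, 300, "+"), "MIRb", "SINE", "MIR",
            500.0, 15.0)
        strict = ScreenConfig(require_inverted=True)
        lax = ScreenConfig(require_inverted=False)
        assert filter_te(["L"], ann, [same_orientation_mir], strict) == []
        assert filter_te(["L"], ann, [same_orientation_mir], lax) == ["L"]


class TestFilterAntisense:
    def _ann(self, lnc_exons, lnc_strand, sense_exons, sense_strand):
        lnc = make_gene(make_tx(lnc_exons, strand=lnc_strand,
                                gene_id="L", tx_id="L.t"))
        sense = make_gene(make_tx(
            sense_exons, strand=sense_strand, gene_id="S", tx_id="S.t",
            biotype="protein_coding",
            cds=[(sense_exons[0][0] + 10, sense_exons[0][0] + 40)],
            start_codon=[(sense_exons[0][0] + 10, sense_exons[0][0] + 13)]))
        return AnnotationSet([lnc, sense])

    def test_single_nucleotide_overlap_kept_at_minoverlap_one(self, cfg):
        ann = self._ann([(0, 100)], "-", [(99, 300)], "+")
        pairs = filter_antisense(["L"], ann, cfg)
        assert [(p.lnc_gene_id, p.sense_gene_id, p.overlap_nt) for p in pairs] \
            == [("L", "S", 1)]

    def test_same_strand_overlap_excluded(self, cfg):
        ann = self._ann([(0, 100)], "+", [(50, 300)], "+")
        assert filter_antisense(["L"], ann, cfg) == []

    def test_abutting_exons_excluded(self, cfg):
        ann = self._ann([(0, 100)], "-", [(100, 300)], "+")
        assert filter_antisense(["L"], ann, cfg) == []


class TestFilterTisOverlap:
    def _pairs_and_ann(self, lnc_exons, codon=(90, 93)):
        lnc = make_gene(make_tx(lnc_exons, strand="-", gene_id="L", tx_id="L.t"))
        sense = make_gene(make_tx([(0, 200)], gene_id="S", tx_id="S.t",
                                  biotype="protein_coding",
                                  cds=[(codon[0], 180)],
                                  start_codon=[codon]))
        ann = AnnotationSet([lnc, sense])
        pairs = filter_antisense(["L"], ann, ScreenConfig())
        return pairs, ann

    def test_full_codon_coverage(self):
        pairs, ann = self._pairs_and_ann([(50, 120)])
        ((_, nt, _),) = filter_tis_overlap(pairs, ann)
        assert nt == 3

    def test_single_base_boundary_coverage(self):
        """LncRNA exon ends one base into the codon: kept with 1 nt."""
        pairs, ann = self._pairs_and_ann([(50, 91)])
        ((_, nt, _),) = filter_tis_overlap(pairs, ann)
        assert nt == 1

    def test_three_prime_utr_only_overlap_dropped(self):
        pairs, ann = self._pairs_and_ann([(150, 190)])
        assert pairs  # antisense overlap exists...
        assert filter_tis_overlap(pairs, ann) == []  # ...but misses the TIS

    def test_noncoding_sense_dropped_with_warning(self, caplog):
        lnc = make_gene(make_tx([(50, 120)], strand="-", gene_id="L", tx_id="L.t"))
        sense = make_gene(make_tx([(0, 200)], gene_id="S", tx_id="S.t",
                                  biotype="protein_coding"))
        ann = AnnotationSet([lnc, sense])
        pairs = filter_antisense(["L"], ann, ScreenConfig())
        with caplog.at_level("WARNING", logger="sineup_screen"):
            assert filter_tis_overlap(pairs, ann) == []
        assert any("no coding isoform" in r.message for r in caplog.records)


class TestRunScreen:
    def test_empty_deg_table_yields_no_candidates(self):
        fx = generate_screen_fixture(reported_candidates_spec(n_decoys=4))
        table = run_screen([], fx.annotation, fx.repeat_hits)
        assert table.pairs == []
        assert table.stage_counts["lncrna"] == 0

    def test_decoys_only_fixture_yields_no_candidates(self):
        from sineup_screen.synthetic_data import VIOLATIONS
        spec = LocusSpec(
            planted=[],
            decoys=[Decoy(violation=v, index=i) for i, v in enumerate(VIOLATIONS)],
            seed=11,
        )
        fx = generate_screen_fixture(spec)
        table = run_screen(fx.deg, fx.annotation, fx.repeat_hits)
        assert table.pairs == []

    def test_monotone_stage_counts(self):
        fx = generate_screen_fixture(reported_candidates_spec())
        counts = run_screen(fx.deg, fx.annotation, fx.repeat_hits).stage_counts
        assert counts["lncrna"] >= counts["embedded_te"] >= counts["tis_overlap"]

    def test_output_invariant_under_input_permutations(self, rng):
        fx = generate_screen_fixture(reported_candidates_spec(n_decoys=10))
        ref = run_screen(fx.deg, fx.annotation, fx.repeat_hits).to_dataframe()
        for _ in range(3):
            deg_perm = [fx.deg[i] for i in rng.permutation(len(fx.deg))]
            hits_perm = [fx.repeat_hits[i]
                         for i in rng.permutation(len(fx.repeat_hits))]
            out = run_screen(deg_perm, fx.annotation, hits_perm).to_dataframe()
            assert out.equals(ref)

    def test_candidate_rows_satisfy_invariants(self):
        fx = generate_screen_fixture(reported_candidates_spec())
        table = run_screen(fx.deg, fx.annotation, fx.repeat_hits)
        for pair in table.pairs:
            assert pair.antisense_overlap_nt >= 1
            assert 1 <= pair.tis_overlap_nt <= 3
            assert pair.lnc_gene.strand != pair.sense_gene.strand
            assert any(te.inverted for te in pair.embedded_tes)

    def test_bound_flags_are_pass_through(self):
        fx = generate_screen_fixture(reported_candidates_spec())
        table = run_screen(fx.deg, fx.annotation, fx.repeat_hits)
        by_lnc = {p.lnc_gene.gene_name: p.bound_flags for p in table.pairs}
        assert by_lnc["RAB11B-AS1"] == (0, 1)
        assert by_lnc["RP11-400F19.6"] == (0, 0)


class TestLoadDegTable:
    def test_tsv_with_aliases_and_bound_column(self, tmp_path):
        path = tmp_path / "deg.tsv"
        path.write_text(
            "EnsID\tGene name\tFC\tPvalue\tReg. Direction\tBound\n"
            "ENSG1\tRAB11B-AS1\t1.8485\t0.00519\tup\t0\n"
            "ENSG2\tST7-AS1\t-1.7671\t0.00991\tdown\t1\n"
        )
        records = load_deg_table(path)
        assert records[0].gene_name == "RAB11B-AS1"
        assert records[0].fold_change == pytest.approx(1.8485)
        assert records[1].direction == "down"
        assert records[1].bound == 1

    def test_log2_scale_converted_to_signed_linear(self, tmp_path):
        path = tmp_path / "deg.tsv"
        path.write_text("gene_id\tlog2FC\tpvalue\nG1\t1.0\t0.01\nG2\t-2.0\t0.01\n")
        records = load_deg_table(path, fc_scale="log2")
        assert records[0].fold_change == pytest.approx(2.0)
        assert records[1].fold_change == pytest.approx(-4.0)
        assert records[1].direction == "down"

    def test_xlsx_dialect(self, tmp_path):
        import pandas as pd
        path = tmp_path / "deg.xlsx"
        pd.DataFrame({
            "gene_id": ["G1", "G2"], "FC": [2.0, -1.5],
            "Pvalue": [0.01, 0.02],
        }).to_excel(path, index=False)
        records = load_deg_table(path)
        assert len(records) == 2
        assert records[1].direction == "down"

    def test_missing_required_column_raises(self, tmp_path):
        path = tmp_path / "deg.tsv"
        path.write_text("gene_id\tsomething\nG1\t1\n")
        with pytest.raises(ValueError, match="fold_change"):
            load_deg_table(path)
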