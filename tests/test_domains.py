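"""Binding/effector domain annotation and deletion-mutant design."""

import numpy as np
import pytest

from sineup_screen.annotation_io import GenomicInterval
from sineup_screen.domains import (
    DomainError,
    annotate_domains,
    compute_binding_domain,
    compute_effector_domain,
    design_constructs,
    genomic_to_transcript_coords,
    make_deletion_mutant,
    transcript_to_genomic,
)
from sineup_screen.repeats import RepeatHit, exonic_te_hits
from sineup_screen.synthetic_data import generate_screen_fixture, reported_candidates_spec

from conftest import make_tx, oracle_binding_domain


def sense_tx(exons=((0, 200),), codon=(90, 93)):
    return make_tx(list(exons), gene_id="S", tx_id="S.t",
                   biotype="protein_coding",
                   cds=[(codon[0], exons[-1][1] - 10)], start_codon=[codon])


def embedded(start, end, tx, name="AluY", fam="Alu"):
    hit = RepeatHit(GenomicInterval("chr1", start, end,
                                    "+" if tx.strand == "-" else "-"),
                    name, "SINE", fam, 1000.0, 10.0)
    (te,) = exonic_te_hits(tx, [hit])
    return te


class TestBindingDomain:
    def test_minimal_codon_only_overlap(self):
        lnc = make_tx([(90, 93)], strand="-", gene_id="L", tx_id="L.t")
        bd, nt = compute_binding_domain(sense_tx(), lnc)
        assert nt == 3
        assert (bd.start, bd.end) == (90, 93)

    def test_contiguous_run_containing_tis_wins(self):
        """Two intersection runs; the BD is the one holding the codon."""
        lnc = make_tx([(50, 120), (150, 180)], strand="-",
                      gene_id="L", tx_id="L.t")
        bd, nt = compute_binding_domain(sense_tx(), lnc)
        assert (bd.start, bd.end, nt) == (50, 120, 70)

    def test_error_when_no_run_contains_codon(self):
        lnc = make_tx([(150, 180)], strand="-", gene_id="L", tx_id="L.t")
        with pytest.raises(DomainError, match="TIS"):
            compute_binding_domain(sense_tx(), lnc)

    def test_matches_perbase_oracle_on_random_pairs(self, rng):
        for _ in range(40):
            cuts = np.sort(rng.choice(np.arange(0, 400), size=6, replace=False))
            exons = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 6, 2)]
            lnc = make_tx(exons, strand="-", gene_id="L", tx_id="L.t")
            stx = sense_tx(exons=((0, 400),), codon=(200, 203))
            expected = oracle_binding_domain(stx, lnc)
            if expected is None:
                with pytest.raises(DomainError):
                    compute_binding_domain(stx, lnc)
            else:
                bd, nt = compute_binding_domain(stx, lnc)
                assert (bd.start, bd.end) == expected
                assert nt == expected[1] - expected[0]

    def test_bd_bounded_by_total_intersection(self):
        from sineup_screen.annotation_io import exonic_intersection
        lnc = make_tx([(50, 120), (150, 180)], strand="-",
                      gene_id="L", tx_id="L.t")
        stx = sense_tx()
        _, nt = compute_binding_domain(stx, lnc)
        assert nt <= exonic_intersection(stx, lnc)[1]


class TestEffectorDomain:
    def test_single_fully_exonic_inverted_alu(self):
        lnc = make_tx([(900, 1400)], strand="-", gene_id="L", tx_id="L.t")
        ed = compute_effector_domain(lnc, [embedded(1000, 1300, lnc)])
        assert ed.ed_len_nt == 300
        assert len(ed.ed_members) == 1

    def test_nested_fram_in_alu_union(self):
        """FRAM [1040,1180) nested in AluY [1000,1222): union is 222 nt."""
        lnc = make_tx([(900, 1400)], strand="-", gene_id="L", tx_id="L.t")
        tes = [embedded(1000, 1222, lnc, name="AluY"),
               embedded(1040, 1180, lnc, name="FRAM")]
        ed = compute_effector_domain(lnc, tes)
        assert (ed.ed_genomic.start, ed.ed_genomic.end) == (1000, 1222)
        assert ed.ed_len_nt == 222
        assert len(ed.ed_members) == 2

    def test_union_length_vs_member_sum(self):
        """Union <= sum of member exonic lengths, equal iff disjoint."""
        lnc = make_tx([(0, 2000)], strand="-", gene_id="L", tx_id="L.t")
        overlapping = [embedded(100, 400, lnc), embedded(300, 600, lnc)]
        ed = compute_effector_domain(lnc, overlapping)
        assert ed.ed_len_nt == 500 < sum(t.exonic_overlap_nt for t in overlapping)
        disjoint = [embedded(1000, 1100, lnc), embedded(1200, 1300, lnc)]
        ed2 = compute_effector_domain(lnc, disjoint)
        assert ed2.ed_len_nt == 100  # nearest-3' cluster only
        assert ed2.secondary  # the other cluster is reported

    def test_cluster_nearest_three_prime_end_selected(self):
        # minus strand: 3' end is the genomic left; cluster at 100 wins
        lnc = make_tx([(0, 2000)], strand="-", gene_id="L", tx_id="L.t")
        tes = [embedded(1500, 1600, lnc), embedded(100, 260, lnc)]
        ed = compute_effector_domain(lnc, tes)
        assert (ed.ed_genomic.start, ed.ed_genomic.end) == (100, 260)
        assert ed.ed_dist_to_3prime_nt == 100

    def test_exon_clipping(self):
        lnc = make_tx([(0, 150), (300, 500)], strand="-", gene_id="L", tx_id="L.t")
        hit = RepeatHit(GenomicInterval("chr1", 100, 350, "+"),
                        "AluY", "SINE", "Alu", 900.0, 9.0)
        (te,) = exonic_te_hits(lnc, [hit])
        ed = compute_effector_domain(lnc, [te])
        assert ed.ed_len_nt == 100  # [100,150) + [300,350)

    def test_empty_te_list_raises(self):
        lnc = make_tx([(0, 100)], strand="-", gene_id="L", tx_id="L.t")
        with pytest.raises(DomainError):
            compute_effector_domain(lnc, [])


class TestCoordinateMapping:
    @pytest.mark.parametrize("strand,g,expected", [
        ("+", (100, 110), (0, 10)),
        ("-", (190, 200), (0, 10)),
    ])
    def test_single_exon_ends(self, strand, g, expected):
        tx = make_tx([(100, 200)], strand=strand)
        iv = GenomicInterval("chr1", *g)
        assert genomic_to_transcript_coords(tx, iv) == expected

    def test_splice_junction_spanning_interval(self):
        tx = make_tx([(0, 10), (20, 30)])
        iv = GenomicInterval("chr1", 5, 25)
        start, end = genomic_to_transcript_coords(tx, iv)
        assert (start, end) == (5, 15)
        assert end - start == 10  # exonic overlap of g

    def test_intronic_interval_raises(self):
        tx = make_tx([(0, 10), (20, 30)])
        with pytest.raises(DomainError, match="exonic"):
            genomic_to_transcript_coords(tx, GenomicInterval("chr1", 12, 18))

    def test_round_trip_identity_on_random_transcripts(self, rng):
        """genomic->transcript->genomic is the identity on exonic intervals."""
        for _ in range(40):
            cuts = np.sort(rng.choice(np.arange(0, 600), size=8, replace=False))
            exons = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 8, 2)]
            strand = "+" if rng.random() < 0.5 else "-"
            tx = make_tx(exons, strand=strand)
            # pick a random exonic sub-interval in transcript space
            lo = int(rng.integers(0, tx.exonic_length - 1))
            hi = int(rng.integers(lo + 1, tx.exonic_length + 1))
            pieces = transcript_to_genomic(tx, (lo, hi))
            assert sum(p.length for p in pieces) == hi - lo
            # map the genomic envelope back: must recover (lo, hi)
            envelope = GenomicInterval(tx.chrom, pieces[0].start, pieces[-1].end)
            assert genomic_to_transcript_coords(tx, envelope) == (lo, hi)


class TestMutantDesign:
    def test_full_deletion(self):
        m = make_deletion_mutant("ACGT", (0, 4))
        assert m.sequence == ""

    def test_internal_deletion(self):
        m = make_deletion_mutant("AAACCCGGGTTT", (3, 6), name="dBD")
        assert m.sequence == "AAAGGGTTT"
        assert m.deleted_tx_interval == (3, 6)

    def test_out_of_range_raises(self):
        with pytest.raises(DomainError):
            make_deletion_mutant("ACGT", (2, 9))

    def test_constructs_on_planted_canonical_locus(self):
        """WT/dBD/dED lengths and prefix+suffix identity on the fixture."""
        fx = generate_screen_fixture(reported_candidates_spec(n_decoys=0))
        ann = fx.annotation
        lnc = ann["ENSG00000269386"].transcripts[0]
        stx = ann["ENSG00000185236"].transcripts[0]
        tes = [t for t in exonic_te_hits(lnc, fx.repeat_hits) if t.inverted]
        dom = annotate_domains(stx, lnc, tes)
        wt, dbd, ded = design_constructs(lnc, fx.genome, dom)
        assert len(wt.sequence) == lnc.exonic_length
        assert len(dbd.sequence) == len(wt.sequence) - dom.bd_len_nt
        assert len(ded.sequence) == len(wt.sequence) - dom.ed_len_nt
        for mut in (dbd, ded):
            s, e = mut.deleted_tx_interval
            assert mut.sequence == wt.sequence[:s] + wt.sequence[e:]

    def test_canonical_geometry_lengths(self):
        """The planted canonical locus reproduces the 96/222-nt domains."""
        fx = generate_screen_fixture(reported_candidates_spec(n_decoys=0))
        ann = fx.annotation
        lnc = ann["ENSG00000269386"].transcripts[0]
        stx = ann["ENSG00000185236"].transcripts[0]
        tes = [t for t in exonic_te_hits(lnc, fx.repeat_hits) if t.inverted]
        dom = annotate_domains(stx, lnc, tes)
        assert dom.bd_len_nt == 96
        assert dom.ed_len_nt == 222
        assert len(dom.ed_members) == 2
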