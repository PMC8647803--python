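# Methods

## The screening model

The screen formalises the structural definition of a natural SINEUP: an
antisense lncRNA whose mature transcript (i) is differentially expressed
in the contrast of interest, (ii) carries an embedded SINE-derived
element in inverted orientation, (iii) overlaps a protein-coding gene on
the opposite strand, and (iv) covers the sense gene's translation
initiation codon. The four predicates are evaluated in that fixed order
and the per-stage survivor counts are part of the output contract, so the
filtering funnel is comparable between runs even though the predicates
commute logically.

Assumptions baked into the model:

* **Gene level in, isoform level inside.** The DEG table and the output
  rows are gene-level; each structural predicate passes if *any* isoform
  (pair) passes, and the best-supporting isoform pair is recorded. One
  output row is emitted per (lncRNA gene, sense gene) pair — a lncRNA
  spanning two coding genes' TISs yields two rows.
* **Differential expression is required of the lncRNA only.** The sense
  gene's statistics, and any regulator-binding flags carried by the input
  table, are reported pass-through, never filtered on (observed candidate
  tables include unregulated sense partners).
* **Domains act in the mature RNA.** TE hits overlapping introns only are
  never accepted, and the exonic overlap/fraction of every accepted hit
  is recorded so stricter exonicity policies are a configuration change.
* **Inversion is relative to the transcript strand**, the convention of
  the inverted-SINEB2 literature; the genomic strand of a hit by itself
  is meaningless here. Whether inversion was required during the original
  gene selection or merely observed in the survivors is ambiguous in the
  source material; the default requires it (`require_inverted=True`),
  with the switch exposed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lncrna_biotypes` | `{lncRNA, antisense, lincRNA}` | biotype labels counted as lncRNA; spans GENCODE versions before/after the biotype merge |
| `te_families` | `{SINE/Alu, SINE/MIR, SINE/B2, SINE/B4}` | accepted (class, family) pairs; Alu includes the FLAM/FRAM monomer names, B2/B4 cover the murine SINEB2 analog |
| `require_inverted` | `True` | require hit strand ≠ transcript strand at stage 2 |
| `minoverlap` | 1 nt | minimal exonic antisense overlap at stage 3 |
| `min_exonic_nt` | 1 nt | minimal exonic footprint of a TE hit (no published threshold exists; the fraction is recorded for stricter policies) |
| `use_gene_spans` | `False` | stage-3 overlap on exon sets; span overlap available because the original implementation's granularity is not documented — stage 4 explicitly uses exon coordinates, so exon sets are the default everywhere |

All genomic arithmetic is 0-based half-open internally; GTF (1-based
closed) and RepeatMasker `.out` (1-based closed, `C` = minus) are
converted at the I/O boundary and restored on re-emission. Only lengths
and overlap counts are convention-sensitive, and those are
convention-free quantities.

## Domain definitions

**BD.** The per-base exonic intersection of the antisense and sense
transcripts is merged into maximal runs; the BD is the run containing at
least one start-codon base (ties on split codons resolved by larger codon
coverage, then leftmost). Defining the BD as one *contiguous* run rather
than the full scattered intersection makes its length well-defined and
matches the single highlighted antisense block of the motivating locus,
whose BD measures 96 nt. When `start_codon` features are absent the codon
is derived by walking 3 bases from the 5′ end of the spliced CDS, which
may split it across an intron.

**ED.** Raw TE hit intervals are clustered first (merged when overlapping
or abutting; `merge_gap_nt` defaults to 0 — the nested FRAM-in-Alu case
needs no gap tolerance), so a hit straddling an intron stays one unit;
each cluster's union is then clipped to the exonic footprint for its
length. With several disjoint clusters, the one nearest the transcript 3′
end is the ED (the canonical configuration) and the rest are reported as
secondary. Nearness to the 3′ end is *reported* as a transcript-coordinate
distance, never enforced. Whether a published ED length refers to the raw
union or the exon clip is ambiguous; both coincide for fully exonic hits,
and the exon-clipped value is primary.

**Constructs.** Deletion mutants are designed in mature (spliced)
transcript coordinates, because the cloned construct is the mature RNA:
ΔBD and ΔED differ from WT exactly by the excised substring (checked by
prefix+suffix identity in tests).

## qPCR and regression choices

* Replicates are averaged on the Cq scale before differencing — standard
  ΔΔCq practice (source material silent on this point); amplification is
  assumed exactly 2-fold per cycle (no efficiency correction).
* The tissue-panel matrix rescales each gene by its maximum so the
  highest-expressing tissue equals 1 (equivalently, ΔΔCq against the
  minimum-ΔCq tissue).
* Regressions are ordinary least squares via `scipy.stats.linregress`;
  both *r* and *R*² are emitted and labelled, since mixed usage of the
  two is common. Slope *p*-values are two-sided; the separate group
  *t*-test utility defaults to one-tailed, matching the unpaired
  one-tailed contrasts used for knockdown-vs-control comparisons.
* Degenerate inputs: < 3 paired finite observations or a zero-variance
  predictor raise immediately rather than returning NaNs.

## What the generators emulate — and what they do not

The locus generator lays out one antisense/sense pair per disjoint
6-kb window on a synthetic contig: a plus-strand coding gene (600-nt
exon, 300-nt CDS, annotated start codon) and a minus-strand lncRNA with a
3′ exon hosting the TE hit(s) and a 5′ exon crossing the sense TIS. The
planted five-pair fixture uses the published candidate fold changes and
*p*-values as its DEG values, and gives the canonical locus the published
geometry: a 96-nt TIS-spanning antisense exon and a FRAM monomer nested
in an inverted Alu with a 222-nt union, 40 nt from the 3′ end. Decoys
instantiate exactly one violation each, one class per filter clause
(wrong biotype, absent from the DEG table, unaccepted family,
non-inverted, intronic TE, same-strand overlap, no overlap, 3′-UTR-only
overlap). Because a locus with no antisense overlap necessarily also
lacks TIS overlap, the generator's self-check asserts the *sequential*
contract: every decoy passes all stages before its declared one and fails
exactly there; planted loci pass all four. TE score/divergence fields are
drawn from plausible ranges (SW 300–3000, divergence 5–25%) purely to
exercise the parser.

The expression generator draws two gene rows from a bivariate normal on
the log scale with the stated population correlation (an exact affine
image at ρ = ±1); the Cq generator shifts the target gene's cycles by
−log₂(fold) and adds i.i.d. Gaussian cycle noise per well, so the ΔΔCq
analysis recovers the planted fold in expectation.

What passing these fixtures does **not** show about real data: the
generator produces single-isoform genes, clean non-overlapping windows,
complete annotation (every sense gene has a start codon), perfectly
formatted inputs, and noise-free structural coordinates. Real screens
contend with multi-isoform genes with conflicting structures, overlapping
gene clusters, missing or version-skewed biotypes, and repeat annotations
that disagree between sources; the configuration surface (biotype set,
family set, inversion/exonicity policy, span-vs-exon overlap) exists
precisely because those choices matter there. Expression fixtures are
bivariate-normal with homogeneous samples — no batch structure, no
count-noise mean–variance relation, no group-specific correlation within
one matrix.

## Problem sizes

The packaged study conditions are desk-scale by construction: the
five-pair fixture plus 30 decoys (70 genes, 37 repeat hits), 100-seed
Monte-Carlo loops for ΔΔCq recovery, 200–300-replicate loops at n = 500
for correlation recovery, and regression sample sizes of n = 14
(knockdown logCPM), n = 74/62 (case/control blood cohort) and n = 1886
(CAGE panel) — the sample sizes implied by the published statistics,
back-solved from the printed *R*²/*r* and *p* pairs where not stated.

## Known limitations

* GTF only (GENCODE dialect); GFF3, liftover and isoform quantification
  are out of scope.
* The screen consumes a DEG table; it never calls differential expression
  itself, and regulator-binding flags are pass-through metadata.
* Repeat discovery is not performed; a RepeatMasker `.out` (or UCSC rmsk
  TSV) track is required input.
* qPCR efficiency correction and multiple-testing control across pairs
  are not implemented (single-pair analyses).
* Orthology search and any wet-lab read-outs (protein quantification,
  blot densitometry) are outside the package's scope.
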