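# sineup-screen

A structural screen for **natural SINEUP antisense lncRNAs** among
differentially expressed genes, with functional-domain annotation,
deletion-construct design, and the co-expression statistics used to
characterise candidate loci.

SINEUPs are natural antisense transcripts (NATs) that **up**-regulate
translation of their sense mRNA through an embedded **SINE** element,
without changing the mRNA's abundance. They are modular: a *binding
domain* (BD) — the region antisense-complementary to the sense mRNA
around its translation-initiation site (TIS), which confers target
specificity — and an *effector domain* (ED) — an embedded SINE-derived
sequence in **inverted** orientation relative to the host transcript
(SINEB2 in mouse; Alu, FRAM or MIR in human), which drives the
translational effect. Because both domains are recognisable from genome
annotation alone, SINEUP-like function can be hypothesised for an
antisense lncRNA purely from its structure. This package implements that
structural reasoning as a tested pipeline, motivated by the study of
lncRNA dysregulation in a *CHD8*-knockdown neural-progenitor model of
autism spectrum disorder, where *RAB11B-AS1* emerged as a natural SINEUP
of *RAB11B*.

## The screen

Starting from a gene-level differential-expression (DEG) table, an
annotation (GTF) and a repeat track (RepeatMasker `.out`), candidates
survive four sequential filters:

1. **lncRNA** — the DEG gene's biotype is in the lncRNA set
   (`{lncRNA, antisense, lincRNA}` by default);
2. **embedded TE** — some isoform carries an exonic SINE of an accepted
   family (SINE/Alu, SINE/MIR, SINE/B2, SINE/B4), by default required to
   be inverted relative to the transcript strand;
3. **antisense overlap** — the lncRNA's exons overlap a protein-coding
   gene on the opposite strand by at least `minoverlap` (default 1) nt;
4. **TIS overlap** — the lncRNA's exons cover ≥ 1 nt of the sense gene's
   start codon.

On a surviving pair, the **BD** is the maximal contiguous run of the
per-base exonic intersection of the two transcripts that contains a
start-codon base, and the **ED** is the exon-clipped union of the
embedded TE hits (merged when overlapping/adjacent, the cluster nearest
the transcript 3′ end). Both are also mapped to mature-transcript
coordinates, from which wild-type, ΔBD and ΔED construct sequences are
emitted for functional testing.

On the expression side the package implements 2^−ΔΔCq relative qPCR
quantification (replicates averaged on the Cq scale; ΔCq against a
reference gene such as *NONO*; ΔΔCq against a calibrator sample),
tissue-panel matrices normalised per gene to the highest-expressing
tissue, and OLS sense/antisense-vs-regulator regressions (slope, Pearson
*r*, *R*², two-sided slope *p*, per sample group).

Because the real inputs are genome-scale downloads, a first-class
synthetic-locus generator builds miniature, fully annotated fixtures:
planted SINEUP-like pairs (including one with the canonical geometry — a
96-nt antisense block spanning the TIS and a FRAM monomer nested in an
inverted Alu with a 222-nt union) plus single-violation decoys, one class
per filter clause. The generator verifies its own truth table against the
screen predicates before writing anything.

## Worked example

```sh
sineup-screen simulate --seed 7 --out fixture/
sineup-screen run --deg fixture/deg.tsv --gtf fixture/annotation.gtf \
    --rmsk fixture/repeats.out --out results/
# -> 5 candidate lncRNA genes

cat results/stage_counts.tsv
# stage               survivors
# deg_input           66
# lncrna              27
# embedded_te         15
# antisense_overlap   8
# tis_overlap         5
# candidate_lnc_genes 5
```

The funnel starts from 66 DEG genes (5 planted antisense/sense pairs plus
30 decoy loci); 27 are lncRNA-biotype DEGs, 15 carry an accepted exonic
inverted SINE, 8 overlap a coding gene in antisense, and exactly the 5
planted lncRNAs also cover their sense start codon.
`results/candidates.tsv` reproduces the candidate-table schema (fold
change, *p*, direction and regulator-binding flags for both genes of each
pair, plus overlap metrics and supporting isoforms).

```sh
sineup-screen domains --pair ENSG00000269386:ENSG00000185236 \
    --gtf fixture/annotation.gtf --rmsk fixture/repeats.out \
    --genome fixture/genome.fa --out domains/
# -> BD 96 nt; ED 222 nt
```

The BD spans 96 nt over the sense start codon and the ED is the 222-nt
union of the nested FRAM/Alu pair, 40 nt from the transcript 3′ end;
`domains/constructs.fa` holds the WT (396 nt), ΔBD (300 nt) and ΔED
(174 nt) sequences.

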