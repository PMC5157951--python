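# Methods

`hoxcis` re-implements, at desk scale, the computational analysis used to
ask whether deleting a Hox-cluster lncRNA locus (a *Hotair*-like antisense
transcript between two posterior *Hoxc* genes) acts *in trans* — on distant
Polycomb targets — or *in cis*, on its immediate chromosomal neighborhood.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## The synthetic dataset

The generator (`hoxcis.simulate`) emulates the study design: six embryonic
tissues (FL, HL, GT, T1, T2, T3), wild-type and deletion genotypes, two
biological replicates each, stranded single-end 100-nt reads under the
dUTP/TruSeq-stranded convention (reads align antisense to their
transcript).

**Locus geometry.** One synthetic chromosome (`chrS`, 1 Mb by default)
carries `Hoxc12` and `Hoxc11` on the Hox strand, the antisense lncRNA
`Hotair` between them with three alternative start sites (TSS1 annotated;
TSS2 and TSS3 upstream, one inside the `Hoxc11` intron), and `AHotair`, a
short Hox-strand lncRNA from a CpG-island promoter. The deleted segment
lies strictly between the two Hox genes and removes the annotated `Hotair`
exons and both strands' termination signals, but not TSS2/TSS3 or the
`AHotair` promoter. In the deletion allele, transcripts from the surviving
antisense start sites extend to near the `Hoxc12` termination site
("Ghostair"), and `AHotair` extends to the `Hoxc11` start ("LAHotair").
The chromosome default is 1 Mb rather than a denser layout so that
background-gene promoters (TSS ± 2 kb) never overlap: the planted ChIP
margins below are only geometrically satisfiable with disjoint promoter
windows.

**Counts.** Gene counts are negative-binomial with mean
`baseline_g · tissuefactor_{g,t} · 2^{lfc(g,t)} · depth_s` and variance
`mu + alpha·mu²`. Background baselines are log-normal (median 60 reads at
the 50 k reference depth, sigma 1); tissue factors are log-normal
(sigma 0.7), shared between genotypes, so tissue identity dominates the
expression structure as in real embryonic dissections. The default
dispersion is `alpha = 0.05` (replicate CV ~22%, typical of bulk RNA-seq
biological replicates); `alpha < 1e-8` switches to Poisson draws. Planted
genotype effects are exact log2 fold changes on the mean. The default
planted effects mirror the cis pattern under study: the downstream Hox
neighbor up-regulated (HL, T3), the upstream one down-regulated (T3), and
`AHotair` increased in the deletion allele; `Hotair` itself is zero in FL
and T1 (it is posteriorly restricted) and absent from the deletion allele.

**Alignments and coverage.** Reads are placed uniformly along each gene's
flattened exon model (spliced across exon gaps); there is no base-level
sequence or quality model — filters act on the integer mismatch tag (NM)
and the CIGAR. Contaminant reads carry ≥3 mismatches or span the
deliberately overlapping gene pair BG0001/BG0002; ~2% of reads map to the
mitochondrial chromosome. SAM records are written in wild-type coordinates
(junction reads are spliced across the deleted segment, as a spliced
aligner would report them); per-sample bedGraph coverage is written in the
sample's own allele coordinate system, where deletion-allele read-through
is contiguous across the collapsed junction, with a liftover table mapping
between systems. Coverage tracks are keyed by *alignment* strand — this
makes flipping the library-strandedness flag exactly swap the two tracks —
and analyses map alignment strand to transcript strand through the
strandedness setting.

**ChIP tracks.** H3K27me3 and input coverage are flat at 0.5 with planted
targets receiving +6–8 units over TSS ± 2 kb (normalized ratio ≥ 8,
coverage ≥ 0.2 at the emitted 20 M totals) and non-targets ≤ 2; satellite
repeat intervals get +40 regardless, reproducing the artifactual
enrichment that motivates the satellite exclusion. One planted target's
promoter contains a satellite, so the exclusion path is always exercised.

## Quantification

Flattened gene models are per-gene disjoint exon unions: protein-coding
genes contribute only `protein_coding` isoforms (`retained_intron`,
`nonsense_mediated_decay` are dropped), Hox-like genes can be pinned to a
canonical isoform, non-coding genes keep all isoforms. A read is counted
for a gene iff it is unique-mapping, has ≤ 2 mismatches and no indel, its
transcript strand matches the gene, ≥ 1 aligned base overlaps the flattened
exons (the minimum overlap is configurable), and no second same-strand gene
also overlaps. Totals for RPKM are unique mapped nuclear reads
(mitochondrial chromosome names configurable, default `chrM`/`MT`);
the mismatch filter is not applied to totals.

**Normalization.** RPKM values are median-scaled across samples against a
standard of the 100 genes with the least expression rank variation
(SD of within-sample average ranks) among genes whose median RPKM lies in
the central 25–75% window — a data-driven surrogate for stable
housekeeping genes. "Rank variation" and the quantile anchor are not
uniquely defined by the procedure's name; SD-of-ranks and the per-gene
median anchor were chosen because both are directly testable, and the
reference level (median across samples of the standard-gene medians) only
shifts all factors by a global constant. After normalization the
standard-gene median is identical in every sample by construction.

## Differential expression

Per tissue and gene, a log-link NB GLM with offsets `log(size factor)`
(median-of-ratios size factors) contrasts intercept+genotype against
intercept-only; the LRT statistic is referred to chi-square, 1 df. Because
genotype is binary, the full model separates into two independent
one-parameter problems, each maximized by bounded scalar optimization of
the exact NB likelihood (dispersion fixed, shared between full and null
fits); this is verified in tests against statsmodels GLM fits to 1e-6.

**Dispersion.** Per-gene method-of-moments on size-factor-normalized
counts, pooled within genotype (so real effects do not inflate it), floored
at 1e-8 — and additionally floored at the across-gene *median* estimate.
With two replicates per group the raw per-gene moment estimate has ~2
degrees of freedom and underestimates dispersion for half the genes, which
makes the plug-in LRT badly anticonservative (measured type-I error ~0.19
at nominal 0.05); the pooled median floor is a deliberately conservative
information-sharing step (in the spirit of the "maximum" sharing mode of
early NB methods) that restores calibration (measured ~0.05–0.07) without
introducing shrinkage of fold changes. No fold-change shrinkage,
independent filtering, or outlier handling is performed; this is a
transparent simplification relative to full DESeq2-style machinery, whose
testable content here is the model contrast, the LRT, and the joint
correction.

P-values from all tissues enter one pooled Benjamini–Hochberg correction
(NA entries excluded from the denominator, preserved in the output).
Classification uses strict thresholds: `up` iff FDR < 0.05 and fold change
> 1.5 (a fold change of exactly 1.5 is `ns`); the FDR threshold is
routinely relaxed to 0.10 for targeted gene families. An optional Wald
test on the genotype coefficient (observed-information standard errors) is
provided as a control.

At 2v2 with dispersion 0.05 and baseline 500, the log2FC estimator's
standard deviation is ~0.33, so no unshrunk estimator can place ≥90% of
estimates within ±0.5 of the truth (~87% is the information-theoretic
ceiling); recovery is therefore assessed as sign correctness at FDR < 0.05
(≥90% achieved), with the ±0.5 fraction checked against a realistic 80%
bound.

## Polycomb target calling

Promoters are TSS − 2 kb upstream windows by default (TSS ± 2 kb as a
robustness mode), from the flattened model's 5' end, clipped to chromosome
bounds. Mean per-base ChIP and input coverage are normalized per million
mapped reads; the ratio uses a pseudocount of 0.01 on the normalized input
mean so empty input stays finite and monotone. A gene is a putative target
iff ratio ≥ 5 **and** normalized ChIP mean ≥ 0.1 (both inclusive) **and**
no Satellite-class repeat (BED name matching "satellite",
case-insensitive) intersects the promoter. Deduplication of ChIP reads is
assumed upstream of the coverage tracks.

## Locus read-through

Named strand-specific regions (Hotair, AHotair, LAHotair, Ghostair) are
quantified with the gene RPKM formula, region length in place of exonic
length, counting strand-matched filtered reads with ≥ 1 base of overlap.
Transcribed segments are maximal runs of per-base normalized coverage
≥ 0.05 (per million mapped reads), merging gaps shorter than 50 bases — a
deliberately simple stand-in for de novo transcript assembly. A segment
"crosses" the deletion when it strictly contains the collapsed junction
coordinate (deletion-allele coordinates) or spans the whole deleted
interval (wild-type coordinates; wild-type transcripts may legitimately
touch the proximal breakpoint without spanning the deletion). Correlations
between locus genes use log2(RPKM + 1); the +1 offset handles exact zeros,
which the expression filter (RPKM > 1 in ≥ 1 sample) does not preclude in
individual samples.

## Exploratory statistics

PCA operates on log2(RPKM + 1) for genes with RPKM > 1 in ≥ 1 sample,
centered per gene, not scaled, via SVD; variance proportions are the
squared singular values. Sample clustering uses Euclidean distances on the
same transform with complete linkage by default (the linkage method is
configurable; none is canonical for this analysis). The GO background list
takes the minimum, over differentially expressed genes, of counts summed
across the relevant samples as an inclusive threshold — the background
therefore always contains the DE genes. Contingency tests are Pearson
chi-square without continuity correction; the lumbar vertebral-formula
test uses the full 3 genotype × 3 class table (which reproduces the
reported p = 0.97; a 2-group variant is available). A plain hypergeometric
over-representation helper is included as generic plumbing; it is not a
re-implementation of any specific GO enrichment server. For the
target-direction contrast, the 2×2 table printed as rounded counts
([[10, 50], [141, 423]]) yields chi-square 2.05, p = 0.152; the reported
p = 0.18 presumably reflects the unrounded underlying table, so both
values are stated and no agreement is forced.

## Problem sizes and reproduction

`scripts/acceptance.py` regenerates everything from scratch at a given
seed: the full 24-sample pipeline at the default configuration (200
background genes, ~50 k reads/sample), a 2000-gene scale-factor recovery
simulation, and the DE calibration suite (500 null genes; five replicates
of 400 null + 100 planted genes). The scale-factor recovery models
technical resequencing of one RNA pool at three depths (×0.5/1/2, Poisson
counting noise, 1 M reads/sample): the planted quantity is a technical
library factor, and biological replicate noise would confound it by
construction. The test suite uses smaller instances of the same
configurations (30 background genes, ~30 k reads/sample for the
alignment-level fixture).

## Limitations

The generator writes no base-level sequences, qualities, or paired-end
records; mapping ambiguity exists only through the NH tag; splice
placement is uniform within flattened models rather than
isoform-resolved. Passing tests therefore demonstrate the correctness of
the counting, normalization, testing, calling and segmentation logic under
the stated generative assumptions — not robustness to alignment artifacts,
fragment bias, or dispersion misspecification in real libraries. The NB
test is deliberately simpler than DESeq2 and will not numerically
reproduce it. Real-data headline quantities that depend on the original
sequencing libraries (per-tissue DE gene counts, PC1 variance shares,
genome-wide target counts, cross-dataset correlations) are out of reach of
the synthetic setting and are not claimed.
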