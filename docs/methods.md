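# Methods

This note documents the models, decision rules and numerical choices
behind `moltseq`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
closed) is converted on read and write, and BED-family formats are
native. The package operates at gene level: multiple transcripts are
collapsed to the union of their exons, and a gene without exon records
is treated as a single exon spanning its body. The TSS is the 5′-most
transcribed base (`start` on `+`, `end − 1` on `−`); the promoter is the
symmetric genomic window `[TSS − 2000, TSS + 2001)`, clipped at the
chromosome edges when a sizes file is provided (without one, no
right-clipping is possible). The downstream region extends a
configurable 3000 bp past the TTS on the gene's strand; this extent is a
convention (ChIPseeker-like), since "downstream" has no universal
definition.

## Consensus peaks and functional regions

Per-sample peak calls are merged by single-linkage: peaks sharing at
least one base (half-open arithmetic) join one consensus record spanning
their union. Each sample's FoldEnrich on a consensus peak is the maximum
over its constituent peaks, and the summit is inherited from the
constituent with the highest FoldEnrich. Merging is idempotent. The rule
is the simplest testable cross-sample matching (it has a brute-force
connected-components oracle); tools differ here and no single convention
is canonical.

Functional-region assignment tests the full peak interval against each
category's region set in the fixed priority order promoter-TSS, 5′UTR,
3′UTR, exon, intron, downstream, distal intergenic; the first overlap
wins, making the assignment a partition. Introns are gene body minus
exons; UTR categories exist only where the annotation provides UTR
records. Using the full interval (rather than the summit) for overlap is
a choice; the summit-based alternative would only matter for peaks
straddling region boundaries.

TSS signal profiles bin the window `[TSS − flank, TSS + flank)` (flank
must be divisible by the bin size) and flip reverse-strand rows so bin 0
is always upstream. Reverse-strand windows are shifted one base so that
a signal *d* bases downstream of the TSS lands in the same oriented bin
on either strand; without the shift the flip is off by one because the
TSS sits on a bin edge. Windows running off the chromosome start keep
zero-filled bins and are flagged.

## Differential peaks (DEPs)

FoldEnrich values are compared between the replicate groups of the two
stages: `mean_a`/`mean_b` are replicate means, and
`log2fc = log2((mean_b + 0.01)/(mean_a + 0.01))` with `b` the
second-named stage, so positive values mean more accessible in the later
stage. A peak absent from every replicate of a condition is untested;
otherwise missing replicates count as FoldEnrich 0 (absence of a peak
call is evidence of no enrichment, not missing data). The p-value is a
Welch two-sample *t*-test on `log2(FE + 0.01)` — a fully specified,
pluggable stand-in for a fitted count-model test, chosen because
FoldEnrich is a continuous ratio whose replicate noise is approximately
lognormal. Zero variance in both groups yields p = 1 at equal means
(p = 0 otherwise). The DEP rule is raw p ≤ 0.05 **and** |log2fc| ≥ 1,
both inclusive; no multiplicity correction is applied to peaks — the
asymmetry with genes (below) is deliberate and kept.

A consequence of the 0.01 pseudocount is that an exactly 2-fold shift at
moderate FoldEnrich gives |log2fc| marginally below 1 and is not called;
the boundary is crossed from about 2.01-fold upward at FoldEnrich ≈ 4.

## Differential genes (DEGs)

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over genes positive in all samples of the comparison). The
fold change is `log2((mean_b + 0.5)/(mean_a + 0.5))` on normalized
condition means. The test is a Wald test of the log2 fold change under a
negative-binomial model: per-condition method-of-moments dispersion
`α = (s² − m)/m²` averaged across conditions and floored at 1e−8; the
variance of each condition mean follows `(m + αm²)/n`; the delta method
transfers it to the log2 scale. The Wald statistic is referred to a *t*
distribution with `n_a + n_b − 2` degrees of freedom rather than a
normal: with three replicates per condition the variance estimate has
few degrees of freedom, and the *t* reference keeps the null
p ≤ 0.05 rate near nominal (the normal reference is anti-conservative at
this sample size). No dispersion shrinkage, independent filtering or
multi-factor design is attempted. P-values are BH-adjusted over tested
genes (all-zero genes are untested); the DEG rule is padj ≤ 0.05 and
|log2fc| ≥ 1, inclusive.

Benjamini–Hochberg is implemented directly from the step-up definition
(`padj_(i) = min_{j≥i} m·p_(j)/j`, capped at 1) and cross-checked in the
test suite against statsmodels and a brute-force oracle.

FPKM is `counts · 10⁹ / (exonic_length · library_size)` with library
sizes taken from mapping totals, not column sums of retained genes.

## Peak-to-gene assignment and IDEGs

The anchor of a peak is its summit when called, else the interval
midpoint (floor). Promoter overlap uses the full peak interval
(interval-language rule); when several promoters overlap, the gene whose
TSS is closest to the anchor wins, with remaining ties broken by
lexicographically smallest gene id. Peaks overlapping no promoter go to
the gene minimizing |anchor − TSS| on the same chromosome, regardless of
distance (the "regardless of distance" rule is read as within-
chromosome; a peak on a gene-free chromosome is reported unmapped). The
assignment is deterministic and has a brute-force whole-genome-scan
oracle in the tests.

IDEGs are the genes significant in the DEG table that are the assigned
gene of at least one significant DEP of the same comparison; a gene
linked by several DEPs yields one record carrying all peak ids. The
up/down classification uses only the RNA-seq fold-change sign; no
concordance between peak and expression direction is required, so
flipping every DEP sign leaves the IDEG set unchanged. Totals always
satisfy total = up + down.

## GO enrichment and signaling pathways

The over-representation test is the one-sided hypergeometric upper tail
with the population defaulting to all annotated genes (configurable to
e.g. all expressed genes). Study genes without any annotation count
toward the study size but can never hit a term, so adding one can only
weaken enrichment. BH runs within each namespace. No length-bias
(Wallenius) weighting is applied and no ancestor closure over the GO
graph is performed — term metadata is a flat table; both would change
K and k in ways that require inputs (gene lengths, a parent table) the
pipeline does not demand. Signaling pathways are the BP terms whose name
contains "signaling pathway" (case-insensitive), reported with their
study-gene membership and ordered by gene count, then p.

## GPCR triage

Candidates are signaling-pathway member genes carrying GO:0004930
("G protein-coupled receptor activity"). Per-tool helix counts are
normalized in two ways before the consensus: segments with reported
probability below 0.5 are discarded (TMHMM-style hydrophobicity-driven
over-predictions, e.g. a spurious N-terminal helix), and multimeric
homology models reported as `n_helices × n_chains` are reduced to the
per-protomer count (non-divisible counts are kept as reported, with a
warning). A protein is a GPCR when at least two tools that produced a
prediction give an effective count of exactly 7; a protein assessed by a
single tool can never qualify ("insufficient evidence"). The rule is
monotone — raising any tool's count to 7 never revokes a call — and is
verified against an exhaustive truth table. Counts from tools without
per-segment probabilities (secondary-structure and homology-model based
predictors) are taken at face value.

## qPCR

Technical replicates are averaged on the Ct scale per (sample, gene)
before differencing. ΔCt is target minus reference within a sample;
ΔΔCt subtracts the arithmetic mean control-group ΔCt, so the control
group's geometric-mean fold is exactly 1. Relative expression is
2^−ΔΔCt; the quantity is invariant to any constant added to both genes
of a sample, and to a global Ct shift. Group comparisons use a pooled-
variance two-tailed Student's *t*-test on the ΔCt values (testing in the
log domain; testing fold changes directly would skew the null). Primer
efficiency is `(10^(−1/slope) − 1) × 100` from the least-squares slope
of Ct against log10(dilution), requiring at least three points and a
negative slope. Efficiency-corrected (Pfaffl) quantification and
multi-reference normalization are out of scope.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design — four stages (C, D, E, A),
three replicates, adjacent comparisons C_vs_D, D_vs_E, E_vs_A, A_vs_C —
with these defaults, which are also the conditions of the acceptance
tests: 2000 genes on 5 chromosomes; promoter-anchored peaks on 80% of
genes plus intergenic background peaks; lognormal FoldEnrich replicate
noise with σ = 0.2 (natural-log scale); NB counts with dispersion 0.05
and lognormal base means (median ≈ 200); ±20% library-size factors;
planted log2 effects of 3 for both accessibility and expression, applied
to the later stage of a comparison on disjoint gene sets (2% of genes
planted as both DEP and DEG per comparison, 3% each as DEP-only and
DEG-only); a 25-gene planted BP term ("G protein-coupled receptor
signaling pathway") hitting 12 true IDEGs of the D_vs_E comparison; 5
planted receptors with (7,7,7) tool counts and decoys whose counts are
drawn from {0..6, 8..12}; Ct noise σ = 0.2 cycles. Because an effect is
planted by multiplying one stage's mean, it is also visible in the
neighbouring comparison that shares the stage; ground truth is therefore
derived from the stage mean matrices (any ≥2-fold stage-to-stage shift),
not from the planting lists, and the true IDEG set is computed by
applying the same mapping rule to the truly differential peak intervals.
All randomness flows from per-stage `default_rng` streams derived from
the seed, so a fixed configuration yields byte-identical files.

What passing the planted-truth tests shows: the decision rules,
thresholds and bookkeeping of the pipeline recover effects of the
planted magnitude under well-behaved noise, and the tests are calibrated
under the null. What they do not show: performance under real ATAC/RNA
noise — fragment-length and Tn5 sequence bias, GC effects, correlated
replicates, peak-calling artifacts, unbalanced library compositions,
annotation errors — none of which the generator models, nor the behavior
of effects near the detection boundary (the planted log2 effect of 3 is
comfortably supra-threshold). Problem sizes in the test suite (300–2000
genes) were chosen to make the statistical properties measurable with
tight Monte Carlo error while keeping the suite fast.

## Known limitations

- The differential tests are deliberate, fully specified stand-ins with
  the same thresholding semantics as a fitted NB framework (DESeq2-class
  tools), not re-implementations of one; absolute p-values will differ
  even where decisions usually agree.
- The nearest-TSS rule links every non-promoter peak to some gene on its
  chromosome; with sparse annotations this inflates peak-gene links and
  hence candidate IDEG sets.
- One gene model per gene id: isoform-level regulation is invisible.
- GO analysis assumes a flat term table; enrichment of parent terms is
  only as good as the provided annotation's propagation.
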