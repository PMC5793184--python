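# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic study does and does not emulate,
and the numerical conventions that make results reproducible.

## Read QC and methylation summaries

Reads are filtered with three rules applied in order: terminal runs of N are
trimmed at both ends, 5′ bases with Phred quality below 10 are trimmed, and
a read is dropped when more than 20% of its remaining bases fall below
Q20. Interior Ns are left alone. The operation is idempotent — filtering a
filtered read changes nothing — which the suite asserts on random reads.

Per-cytosine calls travel as a table of (chrom, 0-based position, strand,
context, methylated count, unmethylated count). On disk the 1-based,
7-column cytosine-report dialect is used; coordinates convert only at file
boundaries, and all interval arithmetic is 0-based half-open. Because CpG
methylation is palindromic, the two strands of a CpG dyad are summed into
one record at the forward-strand C by default; CHG/CHH calls are
strand-specific and never collapsed. Context-level methylation ratios are
call-weighted (Σ methylated / Σ calls) by default, with a site-weighted
variant behind a flag since published summary percentages rarely state which
convention they use.

## DMR calling

Windows are 50 bp on a grid anchored at coordinate 0 of each chromosome, so
the segmentation is deterministic and independent of the data. Only windows
with at least one CpG covered in both samples exist; runs of grid-adjacent
occupied windows merge into candidate regions, and a run longer than 2000 bp
is split greedily left-to-right. Merging precedes testing so that each final
region is tested exactly once and the BH family is well defined.

With a single library per condition a sample-level test is impossible, so
the replicate unit is the per-CpG methylation fraction at positions covered
in both samples, compared with a paired t-test (pairing removes the large
site-to-site component of variance; Welch's two-sample test is available via
`test_kind="welch"`). Regions with zero variance of paired differences get
p = 1.0 — a conservative convention that also covers the degenerate case of
constant nonzero differences, where the t statistic is undefined. Fold
change uses a symmetric pseudocount ε = 0.01 on both pooled levels so a zero
denominator cannot occur; hypomethylated calls use the reciprocal threshold
1/1.25 = 0.8. A minimum of 3 CpGs per region is required for testing
(config-exposed; the source workflow does not state one).

BH and Holm adjustments are implemented directly (step-up with a reverse
cumulative minimum; step-down with a cumulative maximum) and are checked in
the suite against both definitional brute-force oracles and statsmodels.

## Annotation

Feature labelling is non-exclusive: a DMR may simultaneously be exon, UTR
and CGI. Gene-linked classes are derived from the gene models (body, exons
as the mRNA class, introns as the complement, UTRs, CDS, ±2-kb TSS/TTS
flanks, 2-kb upstream promoters and downstream windows); CGI shores (±2 kb)
are computed as an extension. The distribution table reports, per class,
the fraction of features containing at least one DMR and the fraction of
DMRs carrying the label. Overlap queries go through an interval tree and
are verified against a quadratic scan.

Promoters are the 2-kb window upstream of the TSS on the gene's strand,
clipped at chromosome bounds. The same promoter definition is used for
annotation, PMDEG calling and motif scanning.

## Integration and enrichment

MDEG/PMDEG/MDEmiRNA membership needs a single base of overlap — no
minimum-fraction rule. MDEGs use gene-body overlap only; promoter overlap
is the separate PMDEG class, and a gene can be both. The miRNA locus is the
precursor interval from the supplied BED (DMRs are regional, so the
precursor is the natural unit). Enrichment is the hypergeometric upper tail
against a configurable universe (default: all annotated genes), Holm-adjusted
across sets with significance at adjusted p < 0.05.

## Networks

PWM matching uses the min–max-normalised log-odds score: per column,
log2((f_b + c)/(Σf + 4c)) − log2(1/4) with pseudocount c = 0.25, and the
window score is rescaled so the per-column argmax sequence scores exactly 1
and the argmin sequence exactly 0. Hits require relative score strictly
above 0.85 on either strand (the threshold is read as a relative score, not
a match p-value; config-exposed). Ambiguous bases contribute the column
minimum and flag the hit. A TF→gene edge requires the motif hit to overlap
a DMR in that gene's promoter — co-occurrence in the promoter is not
enough — and inherits the DMR's hyper/hypo direction. When several DMRs
overlap one hit the smallest FDR wins, ties broken by larger |log2 fold
change| then leftmost start; the tie-break is deterministic by
construction. De-novo motif discovery is out of scope: the scanner runs
over a supplied PWM library.

The miRNA network keeps rows with target score strictly above 50 whose gene
is an MDEG; PPI edges among kept targets are appended. Exports are SIF,
GraphML (round-trips byte-stably through networkx) and TSV.

## Time course

Rows with SD < 0.5 (ddof = 1) are removed and survivors z-scored. Fuzzy
c-means uses the standard alternating updates — membership
u_ik = 1/Σ_j (d_ik/d_jk)^(2/(m−1)), centers as u^m-weighted means — run to
an objective change below 1e-6. Centers are seeded
distance-squared-proportionally (kmeans++ style) and the best of five
seeded restarts is kept, because plain random-row initialisation routinely
drops one of six well-separated classes. The fuzzifier defaults to m = 1.25:
with z-scored trajectories a small m keeps memberships informative without
collapsing to hard assignment. The cluster count defaults to c = 6 and is
not auto-selected. The membership cutoff 0.6 gates assignment; cluster
centers are classified up / down / transient_up / transient_down with a
±0.05 (z-units) monotonicity tolerance so one noisy step cannot flip a
label. Venn intersections support 2–4 sets and report exclusive region
counts, which therefore sum to the union size.

## Validation and qPCR

Counts are pooled within each cohort group per CpG (the per-CpG Fisher test
implies pooled 2×2 tables); every CpG shared by the groups is tested
two-sided, BH-adjusted across all tested CpGs, and differential at
FDR ≤ 0.05. A candidate region validates with ≥ 5 differential CpGs and a
region-pooled fold change beyond 1.25 (per-CpG fold change was the
alternative reading; region-pooled is implemented and config-exposed).
Candidate regions default to the discovery caller's DMRs. Cross-dataset
overlap needs ≥ 1 bp and flags matched discovery DMRs as validated for
network annotation. Cross-cohort comparison of differential miRNA tables is
an id-plus-direction intersection that reports direction mismatches
explicitly. 2^-ΔΔCt uses per-sample ΔCt = Ct_target − Ct_reference, a
case-minus-control ΔΔCt of group means, and Student's two-sample t-test on
ΔCt values; the reference gene is declared per row, never hard-coded.

## The synthetic study

The generator plants everything downstream stages are asked to find. CpGs
follow a homogeneous Poisson process at 8 per kb, densified six-fold inside
planted DMRs to emulate the CpG-island clustering where differential
methylation concentrates — this also keeps per-region CpG counts in the
range a 50-bp window caller needs. Baseline per-site levels are
Beta(2, 2); inside a planted DMR the low condition is re-drawn uniformly so
that low and low+Δβ both stay inside [0.02, 0.95], making the planted
difference exactly Δβ in expectation without clipping. Counts are
beta-binomial: coverage Poisson(30), and the per-sample success probability
is re-drawn from a Beta with mean μ and dispersion ρ = 0.02
(precision (1−ρ)/ρ), which collapses to plain binomial at ρ = 0 — the suite
checks the binomial variance formula in that limit. Planted directions are
55% hyper / 45% hypo, echoing the observed imbalance in this contrast
without claiming to reproduce it.

Gene bodies (80 genes, 2–4.5 kb) are placed with gaps large enough that
2-kb promoter windows never overlap a neighbouring promoter or body, so a
promoter-planted DMR links to exactly one gene and truth-recovery checks can
demand zero false positives. DMR location classes are 30% promoter, and of
the rest 60% gene-body / 40% intergenic. One intergenic DMR is forced
hypomethylated and hosts a down-regulated miRNA, mirroring the
down-regulated-miRNA-in-hypomethylated-DMR configuration the integration
stage must detect. Eight promoter-DMR genes carry an exact PWM consensus
(width 12, 91/3/3/3 counts) embedded inside the DMR; width 12 keeps the
chance of a spurious ≥ 0.85 relative-score hit inside a planted DMR
negligible. The time course plants six trajectory classes (three rising,
two falling, one rise-then-fall; 100 genes each) plus 200 flat genes whose
row SD sits safely below the 0.5 filter; noise is N(0, 0.2) on an amplitude
of ~4 log-units. The validation cohort re-draws CpG positions and baselines
independently — an independent cohort does not share discovery noise — and
applies the planted effect only to the shared half of the DMRs, with group 1
playing the high condition.

What the generator does not emulate: real human chromosome structure,
sequence-driven CpG islands, bisulfite conversion failure, mapping bias,
read-level errors, replicate structure in the discovery arm (one library per
condition, as in the motivating design), or correlated biological noise
between expression and methylation beyond the planted links. Passing tests
therefore demonstrate that the algorithms recover what their models assume,
not that those models capture every property of real MB-seq data.

## Problem sizes and determinism

The default study is 1 Mb over two chromosomes with ~10,000 CpGs and 50
planted DMRs; the acceptance script runs that discovery arm once, twenty
effect-free replicates for null calibration, an 800-gene time course, a
4-vs-4 validation cohort, and two reduced end-to-end pipeline runs
(400 kb) for the byte-identity check. These sizes were chosen so the whole
analysis re-runs from scratch in a couple of minutes on a single core while
every planted signal remains comfortably detectable.

All randomness flows from one seed through named child generators
(`SeedSequence`-spawned per output stream), so outputs are bit-reproducible
and independent of the order in which stages are invoked. The pipeline
manifest records a configuration hash and SHA-256 of every output file;
re-running with the same configuration reproduces identical checksums.

## Known limitations

The paired t-test on per-CpG fractions treats sites as exchangeable
replicates and ignores spatial autocorrelation of methylation; with a single
library per condition this is the standard compromise, and the null
calibration check (called fraction ≪ 5% of tested regions over 20 null
simulations) bounds its practical false-positive cost on data matching the
generator's assumptions. Window occupancy gaps can split one biological DMR
into several called fragments, which inflates raw call counts relative to
planted region counts; recovery metrics are therefore interval-overlap
based. Motif-hit enrichment of DMR-promoter regions approximates de-novo
discovery by per-PWM hit counting and is flagged as an approximation.
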