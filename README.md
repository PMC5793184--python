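# dmrlink

Differential-methylation analysis for two-condition bisulfite studies, built
around the contrast between androgen-independent and androgen-dependent
prostate-cancer cells: window-based DMR calling from per-CpG methylation
calls, genomic annotation, integration with differential expression of genes
and miRNAs, motif-based TF-target and miRNA-target network construction,
fuzzy c-means clustering of an androgen-deprivation time course, cohort-based
DMR validation, and 2^-ΔΔCt qPCR quantification. Every stage can be exercised
on a built-in synthetic study with planted truth, so the whole pipeline is
testable without any external download.

## Who this is for

Epigenomics and regulatory-genomics analysts who have per-cytosine
methylation call tables (cytosine-report dialect) for two conditions plus the
usual side tables — gene models, feature tracks, differential-expression
results, a PWM library, miRNA target scores, PPI pairs, a time-course matrix,
qPCR Ct values — and want the integrated DMR-centric analysis end to end.

## The core statistics

**DMR calling.** The genome is cut into a fixed 50-bp grid; windows holding a
CpG covered in both samples are kept, runs of adjacent occupied windows are
merged into candidate regions (≤ 2 kb, greedy split), and each region is
tested once. With one library per condition the replicate unit is the per-CpG
methylation fraction β̂ᵢ = mᵢ/(mᵢ+uᵢ), compared between conditions with a
paired t-test across the positions shared by both samples. P-values are
Benjamini–Hochberg adjusted across regions; a region is a DMR when
FDR < 0.05 and the pooled fold change (β_A+ε)/(β_B+ε) exceeds 1.25 or falls
below 1/1.25, with direction hyper iff the ratio exceeds 1.

**Integration.** A DE gene whose body overlaps a DMR (≥ 1 bp) is an MDEG;
with a DMR in its 2-kb upstream promoter it is a PMDEG; a DE miRNA whose
locus overlaps a DMR is an MDEmiRNA. MDEG gene-set enrichment is the
hypergeometric upper tail with Holm correction (adjusted p < 0.05).

**Networks.** Promoters of PMDEGs are scanned on both strands with position
weight matrices; the match score is min–max-normalised log-odds, and hits
with relative score > 0.85 that overlap a promoter DMR create a TF→gene edge
typed by that DMR's direction. The miRNA network keeps predicted targets
with score > 50 that are themselves MDEGs, plus PPI edges among targets.

**Time course.** Rows with SD < 0.5 are dropped, survivors z-scored, and
fuzzy c-means (c = 6, m = 1.25) clusters the trajectories; genes are assigned
at membership ≥ 0.6 and cluster centers classified as rising, falling or
transient.

**Validation.** In an independent two-group cohort, counts are pooled within
groups, each shared CpG gets a two-sided Fisher exact test with BH
correction, and a discovery DMR validates when it holds ≥ 5 differential
CpGs (FDR ≤ 0.05) and a pooled fold change > 1.25 (or < 1/1.25). qPCR panels
are quantified with 2^-ΔΔCt and a two-tailed two-sample t-test on per-sample
ΔCt.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
genome (1 Mb, 80 genes, ~10,000 CpGs, 50 planted DMRs at Δβ = 0.3 and 30×
coverage):

```sh
python analysis/01_simulate_study.py        # writes results/study/
python analysis/02_call_and_annotate_dmrs.py
python analysis/03_integrate_expression.py
python analysis/04_build_networks.py
python analysis/05_timecourse_clusters.py
python analysis/06_validate_cohort.py
```

The second step prints, for the default seed:

```
condition A: overall methylation 50.44% over 9,652 CpGs
condition B: overall methylation 49.41% over 9,652 CpGs
called 88 DMRs (46 hyper, 42 hypo)
planted-DMR recovery: 50/50 (100%)
```

meaning all 50 planted regions were re-found at the published thresholds
(the extra calls are fragments of planted regions split by unoccupied
windows). Step 03 reports `MDEGs: 21  PMDEGs: 15  MDEmiRNAs: 1`, exactly the
planted link classes; step 05 reports an adjusted Rand index of 1.000
against the six planted trajectory classes with all 200 flat genes filtered;
step 06 validates 39 discovery DMRs, consistent with the 28 planted DMRs the
cohort shares by construction (several planted regions are called as more
than one fragment).

The same pipeline is scriptable end to end: `dmrlink run --outdir out
--seed 1` executes all stages and writes a checksummed `manifest.json`;
re-running with the same seed reproduces every output byte for byte. See
`dmrlink --help` for the per-stage subcommands (`simulate`, `qc`, `summary`,
`dmr`, `timecourse`).

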