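#!/usr/bin/env python
"""Generate the synthetic two-condition methylome study used by all
downstream analyses: a ~1 Mb genome with 80 genes, ~10,000 CpGs, 50 planted
DMRs (delta-beta 0.3, 30x coverage), expression tables, a five-point
time-course and a two-group validation cohort. Writes every pipeline input
plus the planted truth under results/study/.
"""

import sys
from pathlib import Path

from dmrlink import io
from dmrlink.methio import write_cytosine_report
from dmrlink.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression_tables,
    simulate_methylome_pair,
    simulate_qpcr_table,
    simulate_timecourse,
    simulate_validation_cohorts,
)

OUT = Path("results/study")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    ann = simulate_annotation(cfg)
    rec_a, rec_b, truth = simulate_methylome_pair(cfg, ann)
    deg, demirna = simulate_expression_tables(cfg, truth, ann)
    matrix, labels = simulate_timecourse(cfg)
    truth.planted_pattern_labels = labels.to_dict()
    group1, group2 = simulate_validation_cohorts(cfg, truth, ann)
    qpcr = simulate_qpcr_table(cfg, truth)

    write_cytosine_report(rec_a, OUT / "calls_condition_a.tsv")
    write_cytosine_report(rec_b, OUT / "calls_condition_b.tsv")
    io.write_bed12(ann.genes, OUT / "genes.bed12")
    io.write_fasta(ann.promoter_seqs, OUT / "promoters.fa")
    io.write_jaspar_pfm(ann.pwms, OUT / "pwms.jaspar")
    io.write_bed6(list(ann.mirna_loci.values()), OUT / "mirna_loci.bed",
                  names=list(ann.mirna_loci))
    for name, track in ann.feature_tracks.items():
        io.write_bed6(track, OUT / f"track_{name}.bed")
    deg.to_csv(OUT / "deg.tsv", sep="\t", index=False)
    demirna.to_csv(OUT / "demirna.tsv", sep="\t", index=False)
    ann.mirna_target_table.to_csv(OUT / "mirna_targets.tsv", sep="\t", index=False)
    ann.ppi_table.to_csv(OUT / "ppi.tsv", sep="\t", index=False)
    io.write_gmt(ann.gene_sets, OUT / "gene_sets.gmt")
    matrix.to_csv(OUT / "timecourse_matrix.tsv", sep="\t")
    qpcr.to_csv(OUT / "qpcr_ct.tsv", sep="\t", index=False)
    for tag, frames in (("g1", group1), ("g2", group2)):
        for i, frame in enumerate(frames):
            write_cytosine_report(frame, OUT / f"cohort_{tag}_sample{i}.tsv")
    truth.to_json(OUT / "truth.json")

    print(f"genome: {sum(ann.chrom_sizes.values()):,} bp over "
          f"{len(ann.chrom_sizes)} chromosomes, {len(ann.genes)} genes")
    print(f"CpGs covered: {len(rec_a):,} (A) / {len(rec_b):,} (B)")
    print(f"planted DMRs: {len(truth.planted_dmrs)} "
          f"({sum(d.direction == 'hyper' for d in truth.planted_dmrs)} hyper)")
    print(f"DE genes: {len(deg)}, DE miRNAs: {len(demirna)}; "
          f"time-course genes: {len(matrix)}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
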