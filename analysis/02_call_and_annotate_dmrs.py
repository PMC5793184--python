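#!/usr/bin/env python
"""Call DMRs between the two conditions with the 50-bp window pipeline
(FDR < 0.05, fold change > 1.25), score recovery of the planted intervals,
and annotate the calls against gene structure and feature tracks.

Reads results/study/ (from 01), writes results/dmrs/.
"""

import json
from pathlib import Path

from dmrlink import io
from dmrlink.annotate import GenomicInterval, annotate_dmr_distribution, overlap_intervals
from dmrlink.dmr import call_dmrs, dmrs_to_frame
from dmrlink.methio import methylation_summary, read_cytosine_report

STUDY = Path("results/study")
OUT = Path("results/dmrs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rec_a = read_cytosine_report(STUDY / "calls_condition_a.tsv")
    rec_b = read_cytosine_report(STUDY / "calls_condition_b.tsv")
    for tag, rec in (("a", rec_a), ("b", rec_b)):
        table = methylation_summary(rec)
        table.to_csv(OUT / f"methylation_summary_{tag}.tsv", sep="\t", index=False)
        overall = table.set_index("context").loc["overall", "percent_methylated"]
        print(f"condition {tag.upper()}: overall methylation {overall:.2f}% "
              f"over {len(rec):,} CpGs")

    dmrs = call_dmrs(rec_a, rec_b)
    frame = dmrs_to_frame(dmrs)
    io.write_dmr_bed(frame, OUT / "dmrs.bed")
    n_hyper = (frame["direction"] == "hyper").sum()
    print(f"called {len(dmrs)} DMRs ({n_hyper} hyper, {len(dmrs) - n_hyper} hypo)")

    truth = json.loads((STUDY / "truth.json").read_text())
    planted = [GenomicInterval(c, s, e)
               for c, s, e in (d["interval"] for d in truth["planted_dmrs"])]
    pairs = overlap_intervals(planted, [d.interval for d in dmrs])
    recovered = len({qi for qi, _ in pairs})
    print(f"planted-DMR recovery: {recovered}/{len(planted)} "
          f"({100 * recovered / len(planted):.0f}%)")

    genes = io.read_bed12(STUDY / "genes.bed12")
    tracks = {}
    for name in ("CGI", "repeat", "enhancer"):
        tracks[name], _ = io.read_bed6(STUDY / f"track_{name}.bed")
    per_dmr, dist = annotate_dmr_distribution(
        [d.interval for d in dmrs], genes, tracks)
    per_dmr.to_csv(OUT / "dmr_labels.tsv", sep="\t", index=False)
    dist.to_csv(OUT / "dmr_distribution.tsv", sep="\t", index=False)
    gene_frac = dist.set_index("feature_class").loc["gene", "frac_features_with_dmr"]
    print(f"fraction of genes containing a DMR: {gene_frac:.2%}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
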