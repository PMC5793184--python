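#!/usr/bin/env python
"""Validate the discovery DMRs in the independent two-group cohort: pool
counts within groups, Fisher-test every shared CpG with BH correction,
validate regions holding >= 5 differential CpGs and fold change > 1.25,
flag cross-dataset overlaps, and quantify the qPCR panel with 2^-ddCt.

Reads results/study/ and results/dmrs/, writes results/validation/.
"""

import json
from pathlib import Path

import pandas as pd

from dmrlink import io
from dmrlink.annotate import GenomicInterval
from dmrlink.methio import read_cytosine_report
from dmrlink.validate import (
    call_validation_dmrs,
    cross_dataset_overlap,
    pool_cohort_counts,
    relative_expression_ddct,
)

STUDY = Path("results/study")
OUT = Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    groups = {}
    for tag in ("g1", "g2"):
        samples = []
        for path in sorted(STUDY.glob(f"cohort_{tag}_sample*.tsv")):
            samples.append(read_cytosine_report(path))
        groups[tag] = pool_cohort_counts(samples)
        print(f"group {tag}: {len(samples)} samples, "
              f"{len(groups[tag]):,} pooled CpGs")

    dmr_frame = io.read_dmr_bed(Path("results/dmrs") / "dmrs.bed")
    candidates = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                  for r in dmr_frame.itertuples()]
    validated = call_validation_dmrs(groups["g1"], groups["g2"], candidates,
                                     min_cpgs=5, fdr=0.05, fc=1.25)
    with open(OUT / "validated_dmrs.bed", "w") as fh:
        for v in validated:
            fh.write(f"{v.interval.chrom}\t{v.interval.start}\t{v.interval.end}"
                     f"\t{v.direction}\t{v.n_diff_cpgs}\t{v.fold_change:.4f}\n")
    print(f"validated {len(validated)} of {len(candidates)} discovery DMRs")

    truth = json.loads((STUDY / "truth.json").read_text())
    n_shared = sum(d["shared_with_validation"] for d in truth["planted_dmrs"])
    print(f"(the cohort shares {n_shared} of {len(truth['planted_dmrs'])} "
          f"planted DMRs by construction)")

    overlap = cross_dataset_overlap(candidates, [v.interval for v in validated])
    overlap.to_csv(OUT / "cross_dataset_overlap.tsv", sep="\t", index=False)

    qpcr = pd.read_csv(STUDY / "qpcr_ct.tsv", sep="\t")
    ddct = relative_expression_ddct(qpcr)
    ddct.to_csv(OUT / "qpcr_results.tsv", sep="\t", index=False)
    for r in ddct.itertuples():
        flag = "*" if r.significant else " "
        print(f"  qPCR {r.target}: fold change {r.fold_change:.2f} "
              f"(p = {r.p_value:.2g}){flag}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
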