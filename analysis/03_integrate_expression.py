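#!/usr/bin/env python
"""Cross the called DMRs with the differential-expression tables: identify
MDEGs (gene body overlap), PMDEGs (promoter overlap) and MDEmiRNAs (locus
overlap), then run hypergeometric gene-set enrichment of the MDEGs with
Holm correction.

Reads results/study/ and results/dmrs/, writes results/integration/.
"""

from pathlib import Path

import pandas as pd

from dmrlink import io
from dmrlink.annotate import build_promoters
from dmrlink.integrate import (
    enrich_gene_sets,
    flag_methylation_overlap,
    identify_pmdegs,
    linked_summary,
)

STUDY = Path("results/study")
OUT = Path("results/integration")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dmr_frame = io.read_dmr_bed(Path("results/dmrs") / "dmrs.bed")
    deg = pd.read_csv(STUDY / "deg.tsv", sep="\t")
    demirna = pd.read_csv(STUDY / "demirna.tsv", sep="\t")
    genes = io.read_bed12(STUDY / "genes.bed12")
    promoters = build_promoters(genes, 2000)

    diff_all = pd.concat([deg, demirna], ignore_index=True)
    linked = flag_methylation_overlap(diff_all, dmr_frame)
    pmdegs = identify_pmdegs(deg, dmr_frame, promoters)
    table = linked_summary(linked + pmdegs)
    table.to_csv(OUT / "methylation_linked.tsv", sep="\t", index=False)

    mdegs = sorted(e.entity_id for e in linked if e.entity_kind == "gene")
    mdemirnas = sorted(e.entity_id for e in linked if e.entity_kind == "miRNA")
    print(f"MDEGs: {len(mdegs)}  PMDEGs: {len(pmdegs)}  "
          f"MDEmiRNAs: {len(mdemirnas)} ({', '.join(mdemirnas)})")
    up = sum(e.direction == "up" for e in linked if e.entity_kind == "gene")
    print(f"MDEG direction split: {up} up / {len(mdegs) - up} down")

    universe = {g.gene_id for g in genes}
    gene_sets = io.read_gmt(STUDY / "gene_sets.gmt")
    enr = enrich_gene_sets(set(mdegs), universe, gene_sets)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    n_sig = int(enr["significant"].sum())
    print(f"gene-set enrichment: {n_sig} of {len(enr)} sets significant "
          f"(Holm-adjusted p < 0.05)")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
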