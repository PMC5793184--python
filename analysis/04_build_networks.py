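#!/usr/bin/env python
"""Scan PMDEG promoters with the PWM library (relative score > 0.85, both
strands), keep motif hits that overlap promoter DMRs, and assemble the
TF-target network; then build the miRNA-target network from predicted
targets (score > 50) restricted to MDEGs, with PPI edges appended.

Reads results/study/, results/dmrs/, writes results/networks/.
"""

from pathlib import Path

import pandas as pd

from dmrlink import io
from dmrlink.annotate import build_promoters
from dmrlink.integrate import flag_methylation_overlap, identify_pmdegs
from dmrlink.networks import (
    build_mirna_target_network,
    build_tf_target_network,
    export_network,
)

STUDY = Path("results/study")
OUT = Path("results/networks")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dmr_frame = io.read_dmr_bed(Path("results/dmrs") / "dmrs.bed")
    deg = pd.read_csv(STUDY / "deg.tsv", sep="\t")
    demirna = pd.read_csv(STUDY / "demirna.tsv", sep="\t")
    genes = io.read_bed12(STUDY / "genes.bed12")
    promoters = build_promoters(genes, 2000)
    promoter_seqs = io.read_fasta(STUDY / "promoters.fa")
    pwms = io.read_jaspar_pfm(STUDY / "pwms.jaspar")
    ppi = pd.read_csv(STUDY / "ppi.tsv", sep="\t")
    scores = pd.read_csv(STUDY / "mirna_targets.tsv", sep="\t")

    pmdeg_ids = sorted(e.entity_id for e in identify_pmdegs(deg, dmr_frame, promoters))
    tf_edges, tf_nodes = build_tf_target_network(
        pmdeg_ids, promoters, promoter_seqs, pwms, dmr_frame,
        deg_table=deg, ppi_table=ppi)
    export_network(tf_edges, tf_nodes, OUT / "tf_network.tsv", "tsv")
    export_network(tf_edges, tf_nodes, OUT / "tf_network.graphml", "graphml")
    n_tf = sum(e.edge_type.startswith("tf_target") for e in tf_edges)
    tfs = {e.source for e in tf_edges if e.edge_type.startswith("tf_target")}
    print(f"TF-target network: {n_tf} TF->PMDEG edges from {len(tfs)} TFs, "
          f"{sum(e.edge_type == 'ppi' for e in tf_edges)} PPI edges")

    diff_all = pd.concat([deg, demirna], ignore_index=True)
    linked = flag_methylation_overlap(diff_all, dmr_frame)
    mdegs = sorted(e.entity_id for e in linked if e.entity_kind == "gene")
    mdemirnas = sorted(e.entity_id for e in linked if e.entity_kind == "miRNA")
    mir_edges, mir_nodes = build_mirna_target_network(
        mdemirnas, scores, mdegs, ppi_table=ppi, deg_table=deg)
    export_network(mir_edges, mir_nodes, OUT / "mirna_network.tsv", "tsv")
    n_mt = sum(e.edge_type == "mirna_target" for e in mir_edges)
    print(f"miRNA-target network: {n_mt} targets of "
          f"{', '.join(mdemirnas) or 'no MDEmiRNA'}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
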