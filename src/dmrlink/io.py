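"""Readers and writers for the plain-text formats flowing through the pipeline.

BED is 0-based half-open; GTF-style attributes are not used — gene models
travel as BED12. FASTA goes through Biopython, position-weight matrices
through the JASPAR PFM dialect (``Bio.motifs`` on the read side).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel, GenomicInterval


def write_bed6(intervals: list[GenomicInterval], path: str | Path,
               names: list[str] | None = None, scores: list[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"feature_{i}"
            score = scores[i] if scores else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed6(path: str | Path) -> tuple[list[GenomicInterval], list[str]]:
    intervals, names = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            names.append(f[3] if len(f) > 3 else f"feature_{len(names)}")
    return intervals, names


def write_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(len(e)) for e in exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in exons) + ","
            thick = g.cds or exons
            thick_start = min(c.start for c in thick) if thick else iv.start
            thick_end = max(c.end for c in thick) if thick else iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start, end, strand), exons=exons)
            )
    return genes


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_jaspar_pfm(pwms: list, path: str | Path) -> None:
    """Write count matrices in JASPAR multi-motif text format."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.tf_name}\n")
            for base, row in zip("ACGT", pwm.matrix):
                values = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{base}  [ {values} ]\n")


def read_jaspar_pfm(path: str | Path) -> list:
    from .networks import PWM  # local import to avoid a cycle

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = [[float(v) for v in m.counts[base]] for base in "ACGT"]
        out.append(PWM(motif_id=m.matrix_id, tf_name=m.name, matrix=counts))
    return out


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write(name + "\t" + name + "\t" + "\t".join(members) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = f[2:]
    return sets


def write_dmr_bed(dmr_frame: pd.DataFrame, path: str | Path) -> None:
    """DMRs as BED6+ with level/fold-change/significance extra columns."""
    import numpy as np

    df = dmr_frame.copy()
    df["name"] = [f"dmr_{i}" for i in range(len(df))]
    df["score"] = -np.log10(df["fdr"].clip(lower=1e-300)) if len(df) else []
    df["bed_strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "bed_strand",
            "level_a", "level_b", "fold_change", "p_value", "fdr",
            "direction", "n_cpgs"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_dmr_bed(path: str | Path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "bed_strand",
            "level_a", "level_b", "fold_change", "p_value", "fdr",
            "direction", "n_cpgs"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    return df
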