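"""Read QC filtering, cytosine-report parsing and context-level summaries.

A set of per-cytosine methylation calls is represented as a pandas DataFrame
with columns ``chrom, pos, strand, context, n_meth, n_unmeth`` (``pos``
0-based). The cytosine-report dialect on disk is the 7-column layout
``chrom, 1-based pos, strand, count-methylated, count-unmethylated, context,
trinucleotide`` (trinucleotide optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

CONTEXTS = ("CpG", "CHG", "CHH")

CPG_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


@dataclass(frozen=True)
class ReadQCParams:
    """Thresholds for bisulfite read filtering.

    5'-terminal bases below ``min_5prime_qual`` and terminal runs of N are
    trimmed; a read is dropped when more than ``max_low_qual_frac`` of its
    remaining bases fall below ``low_qual_threshold``.
    """

    min_5prime_qual: int = 10
    max_low_qual_frac: float = 0.20
    low_qual_threshold: int = 20
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_5prime_qual < 0 or self.low_qual_threshold < 0:
            raise ValueError("quality thresholds must be non-negative")
        if not 0 <= self.max_low_qual_frac <= 1:
            raise ValueError("max_low_qual_frac must be in [0, 1]")


def filter_read(seq: str, qual: str, params: ReadQCParams) -> tuple[str, str] | None:
    """Apply trimming and the low-quality-fraction drop rule to one read.

    Returns the (possibly trimmed) ``(seq, qual)`` or ``None`` if dropped.
    """
    scores = [ord(q) - params.phred_offset for q in qual]
    start, end = 0, len(seq)
    # terminal runs of N at either end
    while start < end and seq[start] in "Nn":
        start += 1
    while end > start and seq[end - 1] in "Nn":
        end -= 1
    # low-quality 5' bases
    while start < end and scores[start] < params.min_5prime_qual:
        start += 1
    # trimming may expose new terminal Ns
    while start < end and seq[start] in "Nn":
        start += 1
    if start >= end:
        return None
    seq, qual, scores = seq[start:end], qual[start:end], scores[start:end]
    n_low = sum(s < params.low_qual_threshold for s in scores)
    if n_low > params.max_low_qual_frac * len(scores):
        return None
    return seq, qual


def filter_reads(
    in_path: str | Path,
    out_path: str | Path,
    params: ReadQCParams | None = None,
) -> dict[str, int]:
    """Filter a FASTQ file; returns a QC report of kept/trimmed/dropped counts."""
    params = params or ReadQCParams()
    report = {"n_input": 0, "n_kept": 0, "n_trimmed": 0, "n_dropped": 0}
    with open(in_path) as fin, open(out_path, "w") as fout:
        try:
            for title, seq, qual in FastqGeneralIterator(fin):
                report["n_input"] += 1
                result = filter_read(seq, qual, params)
                if result is None:
                    report["n_dropped"] += 1
                    continue
                new_seq, new_qual = result
                if len(new_seq) != len(seq):
                    report["n_trimmed"] += 1
                report["n_kept"] += 1
                fout.write(f"@{title}\n{new_seq}\n+\n{new_qual}\n")
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ near record {report['n_input'] + 1}: {exc}"
            ) from exc
    return report


def read_cytosine_report(
    path: str | Path, collapse_cpg_dyads: bool = True
) -> pd.DataFrame:
    """Parse a cytosine report into the internal 0-based call table.

    With ``collapse_cpg_dyads`` the two strands of a CpG dyad (a "+" call at
    p and a "-" call at p+1) are summed into one "+" record at the C of the
    forward strand; CHG/CHH calls are never collapsed (strand-specific).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"],
        usecols=range(7),
        dtype={"chrom": str},
    )
    if df.empty:
        return pd.DataFrame(columns=CPG_COLUMNS)
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"unknown context string(s): {sorted(df.loc[bad, 'context'].unique())}")
    if (df[["n_meth", "n_unmeth"]] < 0).any().any():
        raise ValueError("negative call count in cytosine report")
    df["pos"] = df["pos"].astype(int) - 1  # 1-based file -> 0-based internal
    df = df[CPG_COLUMNS].copy()
    if not collapse_cpg_dyads:
        return df.reset_index(drop=True)

    cpg = df[df["context"] == "CpG"]
    other = df[df["context"] != "CpG"]
    minus = cpg[cpg["strand"] == "-"].copy()
    plus = cpg[cpg["strand"] == "+"].copy()
    # the "-" strand C of a dyad sits one base right of the "+" strand C
    minus["pos"] -= 1
    minus["strand"] = "+"
    merged = (
        pd.concat([plus, minus])
        .groupby(["chrom", "pos"], as_index=False)
        .agg(strand=("strand", "first"), context=("context", "first"),
             n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
    )
    out = pd.concat([merged[CPG_COLUMNS], other], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write the internal call table back to the 7-column 1-based dialect."""
    out = records.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out["tri"] = out["context"].map({"CpG": "CGN", "CHG": "CHG", "CHH": "CHH"})
    out[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def methylation_summary(records: pd.DataFrame, site_weighted: bool = False) -> pd.DataFrame:
    """Per-context and overall methylation ratio, as a percentage.

    Default is call-weighted: ratio = sum(n_meth) / sum(n_meth + n_unmeth).
    ``site_weighted`` averages the per-site fractions instead.
    """
    if records.empty:
        raise ValueError("no records to summarise")
    total_calls = (records["n_meth"] + records["n_unmeth"]).sum()
    if total_calls == 0:
        raise ValueError("undefined methylation ratio: zero total calls")

    def _ratio(sub: pd.DataFrame) -> float:
        calls = sub["n_meth"] + sub["n_unmeth"]
        if site_weighted:
            covered = calls > 0
            return float((sub.loc[covered, "n_meth"] / calls[covered]).mean() * 100)
        return float(sub["n_meth"].sum() / calls.sum() * 100)

    rows = [{"context": ctx, "n_sites": int((records["context"] == ctx).sum()),
             "percent_methylated": _ratio(records[records["context"] == ctx])}
            for ctx in CONTEXTS if (records["context"] == ctx).any()]
    rows.append({"context": "overall", "n_sites": len(records),
                 "percent_methylated": _ratio(records)})
    return pd.DataFrame(rows)
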