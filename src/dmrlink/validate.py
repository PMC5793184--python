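"""Cohort-based DMR validation and qPCR relative-expression quantification.

Validation pools call counts within each group, tests every shared CpG with
a two-sided Fisher exact test, adjusts across CpGs with Benjamini-Hochberg,
and validates a candidate region when it holds at least five differential
CpGs (FDR <= 0.05) and a region-pooled fold change beyond 1.25 (or its
reciprocal). qPCR fold changes use 2^-ddCt with a two-tailed two-sample
t-test on per-sample dCt values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import GenomicInterval, overlap_intervals
from .dmr import adjust_pvalues

logger = logging.getLogger(__name__)


def pool_cohort_counts(samples: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-CpG calls across the samples of one group."""
    stacked = pd.concat(samples, ignore_index=True)
    return (stacked.groupby(["chrom", "pos"], as_index=False)
            [["n_meth", "n_unmeth"]].sum())


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with fixed margins whose
    probability does not exceed the observed table's. All-zero margins give
    p = 1.0 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class ValidatedRegion:
    interval: GenomicInterval
    n_diff_cpgs: int
    n_cpgs: int
    fold_change: float
    direction: str


def call_validation_dmrs(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    candidate_regions: list[GenomicInterval],
    min_cpgs: int = 5,
    fdr: float = 0.05,
    fc: float = 1.25,
    eps: float = 0.01,
) -> list[ValidatedRegion]:
    """Validate candidate regions in a pooled two-group cohort.

    ``group1``/``group2`` are per-CpG counts already pooled within group
    (see :func:`pool_cohort_counts`). Fisher tests run on every CpG shared
    by the groups; BH is applied across all tested CpGs.
    """
    merged = group1.merge(group2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    if merged.empty:
        return []
    p = np.fromiter(
        (fisher_exact_2x2(r.n_meth_1, r.n_unmeth_1, r.n_meth_2, r.n_unmeth_2)
         for r in merged.itertuples()),
        dtype=float, count=len(merged),
    )
    merged = merged.assign(p=p, q=adjust_pvalues(p, "bh"))
    merged["diff"] = merged["q"] <= fdr

    cpg_ivs = [GenomicInterval(r.chrom, int(r.pos), int(r.pos) + 1)
               for r in merged.itertuples()]
    pairs = overlap_intervals(candidate_regions, cpg_ivs)
    by_region: dict[int, list[int]] = {}
    for qi, si in pairs:
        by_region.setdefault(qi, []).append(si)
    out = []
    for ri, region in enumerate(candidate_regions):
        idx = by_region.get(ri)
        if not idx:
            logger.debug("region %s has no covered CpGs; skipped", region)
            continue
        sub = merged.iloc[idx]
        n_diff = int(sub["diff"].sum())
        level1 = sub["n_meth_1"].sum() / (sub["n_meth_1"] + sub["n_unmeth_1"]).sum()
        level2 = sub["n_meth_2"].sum() / (sub["n_meth_2"] + sub["n_unmeth_2"]).sum()
        fold = (level1 + eps) / (level2 + eps)
        if n_diff >= min_cpgs and (fold > fc or fold < 1.0 / fc):
            out.append(ValidatedRegion(region, n_diff, len(sub), float(fold),
                                       "hyper" if fold > 1 else "hypo"))
    return out


def cross_dataset_overlap(
    dmrs_primary: list[GenomicInterval], dmrs_validation: list[GenomicInterval]
) -> pd.DataFrame:
    """Primary DMRs overlapping (>= 1 bp) a validation-cohort DMR.

    Matched primary DMRs come back flagged ``validated=True`` so network
    edges over them can be marked as independently confirmed.
    """
    pairs = overlap_intervals(dmrs_primary, dmrs_validation)
    matched = {qi for qi, _ in pairs}
    rows = [{"primary_idx": i,
             "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "validated": i in matched,
             "validation_idx": ",".join(str(si) for qi, si in pairs if qi == i)}
            for i, iv in enumerate(dmrs_primary)]
    return pd.DataFrame(rows)


def overlap_differential_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Id-plus-direction intersection of two differential tables.

    Rows present in both tables are reported with a ``direction_match``
    flag, so direction conflicts between cohorts surface explicitly.
    """
    a = table_a[["id", "direction"]].rename(columns={"direction": "direction_a"})
    b = table_b[["id", "direction"]].rename(columns={"direction": "direction_b"})
    merged = a.merge(b, on="id")
    merged["direction_match"] = merged["direction_a"] == merged["direction_b"]
    return merged


def relative_expression_ddct(table: pd.DataFrame) -> pd.DataFrame:
    """2^-ddCt fold change and two-sample t-test per target.

    dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt(case) -
    mean dCt(control); fold change = 2^-ddCt. A group with fewer than two
    replicates still yields a fold change but p is NA.
    """
    df = table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for target, sub in df.groupby("target", sort=True):
        case = sub.loc[sub["group"] == "case", "dct"].to_numpy()
        control = sub.loc[sub["group"] == "control", "dct"].to_numpy()
        if len(case) == 0 or len(control) == 0:
            raise ValueError(f"target {target} lacks one of the groups")
        ddct = case.mean() - control.mean()
        fold = 2.0 ** (-ddct)
        if len(case) < 2 or len(control) < 2:
            logger.warning("target %s has <2 replicates in a group; p = NA", target)
            p = np.nan
        else:
            p = float(stats.ttest_ind(case, control, equal_var=True).pvalue)
        rows.append({"target": target, "ddct": float(ddct), "fold_change": float(fold),
                     "p_value": p, "significant": bool(p < 0.05) if np.isfinite(p) else False,
                     "n_case": len(case), "n_control": len(control)})
    return pd.DataFrame(rows)
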