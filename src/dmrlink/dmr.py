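"""Window-based differential methylation calling between two samples.

The genome is partitioned into a fixed 50-bp grid anchored at coordinate 0 of
each chromosome. Windows containing at least one CpG covered in both samples
are kept, runs of grid-adjacent occupied windows are merged into candidate
regions (capped at 2 kb by greedy left-to-right splitting), each region is
tested once with a t-test on per-CpG methylation fractions, p-values are
adjusted with Benjamini-Hochberg across all tested regions, and regions with
FDR below threshold and fold change beyond 1.25 (or its reciprocal) are
reported as DMRs. With a single library per condition the replicate unit of
the t-test is the per-CpG fraction, paired by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmrConfig:
    window_size: int = 50
    max_merged_length: int = 2000
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.25
    min_cpgs_per_region: int = 3
    pseudocount_eps: float = 0.01
    test_kind: str = "paired"  # or "welch"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.max_merged_length < self.window_size:
            raise ValueError("max_merged_length must be >= window_size")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.test_kind not in ("paired", "welch"):
            raise ValueError("test_kind must be 'paired' or 'welch'")


@dataclass
class MethWindow:
    interval: GenomicInterval
    level_a: float
    level_b: float
    positions: np.ndarray  # shared CpG positions
    meth_a: np.ndarray
    total_a: np.ndarray
    meth_b: np.ndarray
    total_b: np.ndarray

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def cpg_levels_a(self) -> np.ndarray:
        return self.meth_a / self.total_a

    @property
    def cpg_levels_b(self) -> np.ndarray:
        return self.meth_b / self.total_b


@dataclass
class Region:
    """A merged candidate region carrying the pooled per-CpG calls."""

    interval: GenomicInterval
    positions: np.ndarray
    meth_a: np.ndarray
    total_a: np.ndarray
    meth_b: np.ndarray
    total_b: np.ndarray
    n_windows: int


@dataclass
class DMR:
    interval: GenomicInterval
    level_a: float
    level_b: float
    fold_change: float
    p_value: float
    fdr: float
    direction: str  # hyper iff fold_change > 1 (A relative to B)
    n_cpgs: int
    n_windows: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chrom": self.interval.chrom,
            "start": self.interval.start,
            "end": self.interval.end,
            "level_a": self.level_a,
            "level_b": self.level_b,
            "fold_change": self.fold_change,
            "p_value": self.p_value,
            "fdr": self.fdr,
            "direction": self.direction,
            "n_cpgs": self.n_cpgs,
            "n_windows": self.n_windows,
        }


def _merge_samples(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    a = records_a[records_a["n_meth"] + records_a["n_unmeth"] > 0]
    b = records_b[records_b["n_meth"] + records_b["n_unmeth"] > 0]
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort")
    merged["total_a"] = merged["n_meth_a"] + merged["n_unmeth_a"]
    merged["total_b"] = merged["n_meth_b"] + merged["n_unmeth_b"]
    return merged


def bin_windows(
    records_a: pd.DataFrame, records_b: pd.DataFrame, config: DmrConfig | None = None
) -> list[MethWindow]:
    """Pool CpG calls into fixed grid windows occupied in both samples."""
    config = config or DmrConfig()
    merged = _merge_samples(records_a, records_b)
    if merged.empty:
        return []
    merged["win"] = merged["pos"] // config.window_size
    windows = []
    for (chrom, win), grp in merged.groupby(["chrom", "win"], sort=True):
        start = int(win) * config.window_size
        windows.append(
            MethWindow(
                interval=GenomicInterval(chrom, start, start + config.window_size),
                level_a=float(grp["n_meth_a"].sum() / grp["total_a"].sum()),
                level_b=float(grp["n_meth_b"].sum() / grp["total_b"].sum()),
                positions=grp["pos"].to_numpy(),
                meth_a=grp["n_meth_a"].to_numpy(),
                total_a=grp["total_a"].to_numpy(),
                meth_b=grp["n_meth_b"].to_numpy(),
                total_b=grp["total_b"].to_numpy(),
            )
        )
    return windows


def merge_windows(windows: list[MethWindow], config: DmrConfig | None = None) -> list[Region]:
    """Merge runs of grid-adjacent occupied windows, splitting runs > 2 kb.

    A run longer than ``max_merged_length`` is split greedily left-to-right
    into consecutive regions of at most that length.
    """
    config = config or DmrConfig()
    max_windows = config.max_merged_length // config.window_size
    windows = sorted(windows, key=lambda w: (w.interval.chrom, w.interval.start))
    runs: list[list[MethWindow]] = []
    for w in windows:
        if (
            runs
            and runs[-1][-1].interval.chrom == w.interval.chrom
            and runs[-1][-1].interval.end == w.interval.start
        ):
            runs[-1].append(w)
        else:
            runs.append([w])
    regions = []
    for run in runs:
        for i in range(0, len(run), max_windows):
            chunk = run[i : i + max_windows]
            regions.append(
                Region(
                    interval=GenomicInterval(
                        chunk[0].interval.chrom,
                        chunk[0].interval.start,
                        chunk[-1].interval.end,
                    ),
                    positions=np.concatenate([w.positions for w in chunk]),
                    meth_a=np.concatenate([w.meth_a for w in chunk]),
                    total_a=np.concatenate([w.total_a for w in chunk]),
                    meth_b=np.concatenate([w.meth_b for w in chunk]),
                    total_b=np.concatenate([w.total_b for w in chunk]),
                    n_windows=len(chunk),
                )
            )
    return regions


def region_statistics(
    region: Region, config: DmrConfig | None = None
) -> tuple[float, float, float, float]:
    """Pooled levels, fold change and t-test p-value for one region.

    Fold change is ``(level_a + eps) / (level_b + eps)``; p comes from a
    two-sided t-test on the per-CpG fractions (paired by position by default).
    A region with zero variance of differences gets p = 1.0 (never
    significant) rather than NaN.
    """
    config = config or DmrConfig()
    eps = config.pseudocount_eps
    level_a = float(region.meth_a.sum() / region.total_a.sum())
    level_b = float(region.meth_b.sum() / region.total_b.sum())
    fold_change = (level_a + eps) / (level_b + eps)
    fa = region.meth_a / region.total_a
    fb = region.meth_b / region.total_b
    if config.test_kind == "paired":
        diffs = fa - fb
        if np.allclose(diffs.std(ddof=0), 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(fa, fb).pvalue)
    else:
        if np.allclose(fa.std(ddof=0), 0.0) and np.allclose(fb.std(ddof=0), 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(fa, fb, equal_var=False).pvalue)
    if np.isnan(p):
        p = 1.0
    return level_a, level_b, float(fold_change), p


def adjust_pvalues(p: list[float] | np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (step-up) or Holm (step-down) adjusted p-values.

    Returned in input order, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    if method == "bh":
        adj = ranked * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
    elif method == "holm":
        adj = ranked * (m - np.arange(m))
        adj = np.maximum.accumulate(adj)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_dmrs(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    config: DmrConfig | None = None,
) -> list[DMR]:
    """Full window pipeline: bin, merge, test, adjust, threshold.

    A region is a DMR when its BH FDR is below ``fdr_threshold`` and its fold
    change exceeds ``fc_threshold`` or falls below its reciprocal; direction
    is hyper (A above B) iff fold change > 1.
    """
    config = config or DmrConfig()
    windows = bin_windows(records_a, records_b, config)
    regions = merge_windows(windows, config)
    tested, stats_rows = [], []
    n_skipped = 0
    for region in regions:
        if len(region.positions) < config.min_cpgs_per_region:
            n_skipped += 1
            continue
        tested.append(region)
        stats_rows.append(region_statistics(region, config))
    if not tested:
        logger.warning("no testable regions (skipped %d below min CpG count)", n_skipped)
        return []
    fdrs = adjust_pvalues([row[3] for row in stats_rows], "bh")
    dmrs = []
    for region, (la, lb, fc, p), fdr in zip(tested, stats_rows, fdrs):
        if fdr >= config.fdr_threshold:
            continue
        if not (fc > config.fc_threshold or fc < 1.0 / config.fc_threshold):
            continue
        dmrs.append(
            DMR(
                interval=region.interval,
                level_a=la,
                level_b=lb,
                fold_change=fc,
                p_value=p,
                fdr=float(fdr),
                direction="hyper" if fc > 1 else "hypo",
                n_cpgs=len(region.positions),
                n_windows=region.n_windows,
            )
        )
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "level_a", "level_b", "fold_change",
            "p_value", "fdr", "direction", "n_cpgs", "n_windows"]
    return pd.DataFrame([d.to_dict() for d in dmrs], columns=cols)
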