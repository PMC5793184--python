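"""Fuzzy c-means clustering of time-course expression and set intersections.

Rows with standard deviation below a floor (default 0.5, the conventional
filter for androgen-deprivation array trajectories) are removed and the
survivors z-scored. Clustering is standard fuzzy c-means: membership
u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)) and centers are u^m-weighted means,
alternated until the objective stabilises. A gene is assigned to its argmax
cluster only when the maximum membership reaches a cutoff (default 0.6);
cluster centers are classified as up / down / transient by their shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FuzzyClustering:
    c: int
    m: float
    centers: np.ndarray  # c x t
    membership: np.ndarray  # n x c, rows sum to 1
    objective_trace: list[float]
    gene_ids: list[str]
    n_iter: int


@dataclass
class ClusterAssignment:
    gene_id: str
    cluster: int | None  # None = unassigned
    max_membership: float
    pattern: str = "other"


def preprocess_timecourse(matrix: pd.DataFrame, min_sd: float = 0.5) -> pd.DataFrame:
    """Drop low-variance rows (SD < min_sd, ddof=1) and z-score the rest."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = matrix.std(axis=1, ddof=1)
    kept = matrix[sd >= min_sd]
    if kept.empty:
        raise ValueError("all rows removed by the minimum-SD filter")
    z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=1), axis=0)
    return z


def _dsq_seed(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-squared-proportional center seeding (kmeans++ style)."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(((x[:, None, :] - np.asarray(centers)[None]) ** 2).sum(axis=2), axis=1)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centers.append(x[rng.choice(n, p=probs)])
    return np.asarray(centers, dtype=float)


def fuzzy_cmeans(
    matrix: pd.DataFrame,
    c: int,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 5,
) -> FuzzyClustering:
    """Seeded fuzzy c-means; best of ``n_init`` D^2-seeded restarts."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    best: FuzzyClustering | None = None
    for restart in range(n_init):
        result = _fuzzy_cmeans_once(matrix, c, m, seed + 7919 * restart, tol, max_iter)
        if best is None or result.objective_trace[-1] < best.objective_trace[-1]:
            best = result
    return best


def _fuzzy_cmeans_once(
    matrix: pd.DataFrame,
    c: int,
    m: float,
    seed: int,
    tol: float,
    max_iter: int,
) -> FuzzyClustering:
    if c < 1:
        raise ValueError("c must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    if c > n:
        raise ValueError("more clusters than rows")
    rng = np.random.default_rng(seed)
    centers = _dsq_seed(x, c, rng) + rng.normal(0, 1e-9, (c, x.shape[1]))
    trace: list[float] = []
    exponent = 2.0 / (m - 1.0)
    u = np.full((n, c), 1.0 / c)
    for it in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u[rows_zero] = 0.0
            u[rows_zero, np.argmax(zero[rows_zero], axis=1)] = 1.0
        um = u**m
        denom = um.sum(axis=0)
        if np.any(denom < 1e-300):
            # a cluster lost all weight: re-jitter its center and continue
            dead = np.nonzero(denom < 1e-300)[0]
            logger.warning("re-seeding %d degenerate center(s) at iter %d",
                           len(dead), it)
            centers[dead] = x[rng.choice(n, len(dead), replace=False)]
            continue
        centers = (um.T @ x) / denom[:, None]
        obj = float((um * d2).sum())
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < tol:
            break
    return FuzzyClustering(c=c, m=m, centers=centers, membership=u,
                           objective_trace=trace, gene_ids=list(matrix.index),
                           n_iter=len(trace))


def classify_center(center: np.ndarray, tol: float = 0.05) -> str:
    """up / down / transient_up / transient_down / other, with a small
    monotonicity tolerance (z-units) so noise cannot flip a label."""
    diffs = np.diff(center)
    net = center[-1] - center[0]
    if np.all(diffs >= -tol) and net > 0:
        return "up"
    if np.all(diffs <= tol) and net < 0:
        return "down"
    interior = center[1:-1]
    if len(interior) and interior.max() > max(center[0], center[-1]):
        if interior.argmax() + 1 not in (0, len(center) - 1):
            return "transient_up"
    if len(interior) and interior.min() < min(center[0], center[-1]):
        return "transient_down"
    return "other"


def assign_and_classify(
    clustering: FuzzyClustering, membership_min: float = 0.6
) -> list[ClusterAssignment]:
    """Assign each gene to its argmax cluster iff membership >= cutoff."""
    patterns = [classify_center(clustering.centers[k]) for k in range(clustering.c)]
    out = []
    for i, gid in enumerate(clustering.gene_ids):
        k = int(np.argmax(clustering.membership[i]))
        mmax = float(clustering.membership[i, k])
        if mmax >= membership_min:
            out.append(ClusterAssignment(gid, k, mmax, patterns[k]))
        else:
            out.append(ClusterAssignment(gid, None, mmax, "unassigned"))
    return out


def assignments_to_frame(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.gene_id, -1 if a.cluster is None else a.cluster, a.max_membership,
          a.pattern) for a in assignments],
        columns=["gene_id", "cluster", "max_membership", "pattern"],
    )


def intersect_gene_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """Counts and members for every region of the 2-4 set Venn partition.

    Region counts are exclusive (elements in exactly that combination), so
    they sum to the size of the union.
    """
    if not 2 <= len(named_sets) <= 4:
        raise ValueError("intersect_gene_sets supports 2-4 sets")
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    universe = set().union(*sets.values())
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            rows.append({"region": "&".join(combo), "n_sets": r,
                         "count": len(inside),
                         "members": ",".join(sorted(map(str, inside)))})
    return pd.DataFrame(rows)
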