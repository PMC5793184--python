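"""PWM promoter scanning and regulatory-network construction.

The motif score is the min-max-normalised log-odds ("relative") score: a
window matching the per-column argmax everywhere scores 1.0, the per-column
argmin everywhere 0.0, and hits are kept when the relative score exceeds a
threshold (default 0.85) on either strand. A TF->gene edge requires the
motif hit in the gene's promoter to overlap a DMR lying in that promoter;
the edge inherits that DMR's methylation direction. The miRNA network keeps
predicted targets with score > 50 that are themselves methylation-linked
DEGs, then appends protein-protein interactions among the kept targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .annotate import GenomicInterval, overlap_intervals

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position count/frequency matrix, rows A, C, G, T."""

    motif_id: str
    tf_name: str
    matrix: list[list[float]]  # 4 x w

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError("PWM must be 4 x w with w >= 4")
        if np.any(m.sum(axis=0) == 0):
            raise ValueError("PWM has an all-zero column")

    @property
    def width(self) -> int:
        return len(self.matrix[0])

    @property
    def consensus(self) -> str:
        m = np.asarray(self.matrix)
        return "".join("ACGT"[i] for i in m.argmax(axis=0))


@dataclass
class MotifHit:
    pwm_id: str
    tf_name: str
    offset: int  # forward-axis, sequence-relative
    strand: str
    relative_score: float
    width: int
    has_ambiguous: bool = False


@dataclass
class RegulatoryEdge:
    source: str
    target: str
    edge_type: str  # tf_target_hyper | tf_target_hypo | mirna_target | ppi
    validated: bool = False
    attrs: dict = field(default_factory=dict)


def _score_matrix(pwm: PWM, pseudocount: float = 0.25) -> np.ndarray:
    """4 x w per-base log2-odds against the uniform background."""
    m = np.asarray(pwm.matrix, dtype=float) + pseudocount
    freqs = m / m.sum(axis=0, keepdims=True)
    return np.log2(freqs) - np.log2(0.25)


def pwm_relative_score(pwm: PWM, window: str, pseudocount: float = 0.25
                       ) -> tuple[float, bool]:
    """Min-max-normalised log-odds score of one window; flags ambiguous bases.

    An N (or other ambiguity code) contributes the column's minimum score.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    sm = _score_matrix(pwm, pseudocount)
    smin, smax = sm.min(axis=0).sum(), sm.max(axis=0).sum()
    score = 0.0
    ambiguous = False
    for j, base in enumerate(window.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            score += sm[:, j].min()
            ambiguous = True
        else:
            score += sm[idx, j]
    return float((score - smin) / (smax - smin)), ambiguous


def scan_sequence(pwm: PWM, seq: str, threshold: float = 0.85,
                  pseudocount: float = 0.25) -> list[MotifHit]:
    """Score every offset on both strands; keep hits strictly above threshold.

    Reverse-strand hit offsets are reported on the forward axis of ``seq``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    w = pwm.width
    seq = seq.upper()
    if len(seq) < w:
        return []
    sm = _score_matrix(pwm, pseudocount)
    smin, smax = sm.min(axis=0).sum(), sm.max(axis=0).sum()
    col_min = sm.min(axis=0)

    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    hits: list[MotifHit] = []
    for strand in ("+", "-"):
        if strand == "+":
            c = codes
        else:
            rc = seq.translate(_COMPLEMENT)[::-1]
            c = np.full(len(rc), -1, dtype=np.int8)
            arr = np.frombuffer(rc.encode(), dtype=np.uint8)
            for base, idx in _BASE_INDEX.items():
                c[arr == ord(base)] = idx
        n_off = len(c) - w + 1
        win = np.lib.stride_tricks.sliding_window_view(c, w)
        known = win >= 0
        scores = np.where(known, sm[np.clip(win, 0, 3), np.arange(w)], col_min).sum(axis=1)
        rel = (scores - smin) / (smax - smin)
        for off in np.nonzero(rel > threshold)[0]:
            fwd_off = int(off) if strand == "+" else len(seq) - int(off) - w
            hits.append(MotifHit(pwm.motif_id, pwm.tf_name, fwd_off, strand,
                                 float(rel[off]), w,
                                 has_ambiguous=bool(~known[off].all())))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _pick_dmr(dmr_frame: pd.DataFrame, idx: list[int]) -> pd.Series:
    """Deterministic tie-break when several DMRs overlap one motif hit:
    smallest FDR wins, then larger |log2 fold change|, then leftmost."""
    sub = dmr_frame.iloc[idx].copy()
    sub["abs_l2fc"] = np.abs(np.log2(sub["fold_change"].clip(lower=1e-12)))
    sub = sub.sort_values(["fdr", "abs_l2fc", "start"],
                          ascending=[True, False, True], kind="mergesort")
    return sub.iloc[0]


def build_tf_target_network(
    pmdeg_ids: list[str],
    promoters: dict[str, GenomicInterval],
    promoter_seqs: dict[str, str],
    pwms: list[PWM],
    dmr_frame: pd.DataFrame,
    deg_table: pd.DataFrame | None = None,
    ppi_table: pd.DataFrame | None = None,
    threshold: float = 0.85,
) -> tuple[list[RegulatoryEdge], pd.DataFrame]:
    """TF->PMDEG edges where a motif hit overlaps a promoter DMR.

    Edge direction (hyper/hypo) comes from the overlapped DMR; TF nodes are
    annotated up/down/not-differential from the DEG table; PPI edges among
    network targets are appended.
    """
    dmr_ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
               for r in dmr_frame.itertuples()]
    deg_dir = {}
    if deg_table is not None and len(deg_table):
        deg_dir = dict(zip(deg_table["id"], deg_table["direction"]))
    edges: list[RegulatoryEdge] = []
    for gid in pmdeg_ids:
        prom = promoters.get(gid)
        seq = promoter_seqs.get(gid)
        if prom is None or seq is None:
            logger.warning("no promoter sequence for %s; skipped", gid)
            continue
        for pwm in pwms:
            if not pwm.tf_name:
                logger.warning("PWM %s lacks a TF name; skipped", pwm.motif_id)
                continue
            hits = scan_sequence(pwm, seq, threshold)
            best = None
            for hit in hits:
                hit_iv = GenomicInterval(prom.chrom, prom.start + hit.offset,
                                         prom.start + hit.offset + hit.width)
                pairs = overlap_intervals([hit_iv], dmr_ivs)
                if not pairs:
                    continue
                d = _pick_dmr(dmr_frame, [si for _, si in pairs])
                if best is None or hit.relative_score > best[0].relative_score:
                    best = (hit, d)
            if best is not None:
                hit, d = best
                edges.append(RegulatoryEdge(
                    source=pwm.tf_name, target=gid,
                    edge_type=f"tf_target_{d['direction']}",
                    attrs={"relative_score": hit.relative_score,
                           "dmr": f"{d['chrom']}:{int(d['start'])}-{int(d['end'])}"},
                ))
    targets = {e.target for e in edges}
    if ppi_table is not None:
        for r in ppi_table.itertuples():
            if r.protein_a in targets and r.protein_b in targets:
                edges.append(RegulatoryEdge(r.protein_a, r.protein_b, "ppi"))
    nodes = _node_table(edges, deg_dir)
    return edges, nodes


def build_mirna_target_network(
    mdemirna_ids: list[str],
    target_scores: pd.DataFrame,
    mdeg_ids: list[str],
    ppi_table: pd.DataFrame | None = None,
    min_score: float = 50.0,
    deg_table: pd.DataFrame | None = None,
) -> tuple[list[RegulatoryEdge], pd.DataFrame]:
    """miRNA->target edges for predicted targets (score > 50) that are MDEGs."""
    mdeg_set = set(mdeg_ids)
    edges: list[RegulatoryEdge] = []
    for mid in mdemirna_ids:
        rows = target_scores[target_scores["mirna"] == mid]
        if rows.empty:
            logger.warning("miRNA %s absent from target score table", mid)
            continue
        kept = rows[(rows["score"] > min_score) & rows["gene"].isin(mdeg_set)]
        for r in kept.itertuples():
            edges.append(RegulatoryEdge(mid, r.gene, "mirna_target",
                                        attrs={"score": float(r.score)}))
    targets = {e.target for e in edges}
    if ppi_table is not None:
        for r in ppi_table.itertuples():
            if r.protein_a in targets and r.protein_b in targets:
                edges.append(RegulatoryEdge(r.protein_a, r.protein_b, "ppi"))
    deg_dir = {}
    if deg_table is not None and len(deg_table):
        deg_dir = dict(zip(deg_table["id"], deg_table["direction"]))
    return edges, _node_table(edges, deg_dir)


def _node_table(edges: list[RegulatoryEdge], deg_dir: dict[str, str]) -> pd.DataFrame:
    names: list[str] = []
    for e in edges:
        for n in (e.source, e.target):
            if n not in names:
                names.append(n)
    return pd.DataFrame({
        "node": names,
        "direction": [deg_dir.get(n, "not_differential") for n in names],
    })


def to_networkx(edges: list[RegulatoryEdge], nodes: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    for r in nodes.itertuples():
        g.add_node(r.node, direction=r.direction)
    for e in edges:
        g.add_edge(e.source, e.target, edge_type=e.edge_type,
                   validated=str(e.validated),
                   **{k: str(v) for k, v in e.attrs.items()})
    return g


def export_network(edges: list[RegulatoryEdge], nodes: pd.DataFrame,
                   path, fmt: str = "tsv") -> None:
    """Lossless export of the typed network (sif / graphml / tsv)."""
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.source}\t{e.edge_type}\t{e.target}\n")
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(edges, nodes), path)
    elif fmt == "tsv":
        pd.DataFrame(
            [(e.source, e.target, e.edge_type, e.validated) for e in edges],
            columns=["source", "target", "edge_type", "validated"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
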