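"""Methylation-expression integration and gene-set enrichment.

A differentially expressed gene whose body overlaps at least one DMR is an
MDEG; one whose promoter overlaps a DMR is a PMDEG (a gene can be both); a
differentially expressed miRNA whose locus overlaps a DMR is an MDEmiRNA.
Overlap requires a single base. Enrichment is the hypergeometric upper tail
with Holm adjustment across sets (significance at adjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .annotate import GenomicInterval, overlap_intervals
from .dmr import adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass
class MethylationLinkedEntity:
    entity_id: str
    entity_kind: str  # gene | miRNA
    direction: str  # up | down
    link_class: str  # body | promoter | locus
    linked_dmrs: list[int] = field(default_factory=list)  # row indices into the DMR table
    linked_dmr_directions: list[str] = field(default_factory=list)


def _diff_intervals(diff: pd.DataFrame) -> list[GenomicInterval]:
    out = []
    for r in diff.itertuples():
        out.append(GenomicInterval(str(r.chrom), int(r.start), int(r.end)))
    return out


def _dmr_intervals(dmr_frame: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in dmr_frame.itertuples()]


def flag_methylation_overlap(
    diff: pd.DataFrame, dmr_frame: pd.DataFrame
) -> list[MethylationLinkedEntity]:
    """MDEGs (gene-body overlap) and MDEmiRNAs (locus overlap).

    ``diff`` rows need columns id, kind, chrom, start, end, direction.
    """
    usable = diff.dropna(subset=["chrom", "start", "end"])
    if len(usable) < len(diff):
        logger.warning("skipped %d records with unresolvable loci",
                       len(diff) - len(usable))
    pairs = overlap_intervals(_diff_intervals(usable), _dmr_intervals(dmr_frame))
    by_query: dict[int, list[int]] = {}
    for qi, si in pairs:
        by_query.setdefault(qi, []).append(si)
    out = []
    rows = usable.reset_index(drop=True)
    for qi, dmr_idx in sorted(by_query.items()):
        r = rows.iloc[qi]
        out.append(MethylationLinkedEntity(
            entity_id=r["id"],
            entity_kind=r["kind"],
            direction=r["direction"],
            link_class="body" if r["kind"] == "gene" else "locus",
            linked_dmrs=sorted(dmr_idx),
            linked_dmr_directions=[dmr_frame.iloc[i]["direction"] for i in sorted(dmr_idx)],
        ))
    return out


def identify_pmdegs(
    diff_genes: pd.DataFrame,
    dmr_frame: pd.DataFrame,
    promoters: dict[str, GenomicInterval],
) -> list[MethylationLinkedEntity]:
    """Differentially expressed genes with a DMR in their promoter."""
    genes = diff_genes[diff_genes["kind"] == "gene"].reset_index(drop=True)
    prom_ivs, keep_rows = [], []
    for i, r in genes.iterrows():
        prom = promoters.get(r["id"])
        if prom is None:
            logger.warning("gene %s has no promoter; skipped", r["id"])
            continue
        prom_ivs.append(prom)
        keep_rows.append(i)
    pairs = overlap_intervals(prom_ivs, _dmr_intervals(dmr_frame))
    by_query: dict[int, list[int]] = {}
    for qi, si in pairs:
        by_query.setdefault(qi, []).append(si)
    out = []
    for qi, dmr_idx in sorted(by_query.items()):
        r = genes.iloc[keep_rows[qi]]
        out.append(MethylationLinkedEntity(
            entity_id=r["id"], entity_kind="gene", direction=r["direction"],
            link_class="promoter", linked_dmrs=sorted(dmr_idx),
            linked_dmr_directions=[dmr_frame.iloc[i]["direction"] for i in sorted(dmr_idx)],
        ))
    return out


def linked_summary(entities: list[MethylationLinkedEntity]) -> pd.DataFrame:
    """Per-direction / per-DMR-direction counts of linked entities."""
    rows = []
    for e in entities:
        rows.append({
            "entity_id": e.entity_id,
            "entity_kind": e.entity_kind,
            "direction": e.direction,
            "link_class": e.link_class,
            "n_linked_dmrs": len(e.linked_dmrs),
            "n_hyper": sum(d == "hyper" for d in e.linked_dmr_directions),
            "n_hypo": sum(d == "hypo" for d in e.linked_dmr_directions),
        })
    return pd.DataFrame(rows, columns=["entity_id", "entity_kind", "direction",
                                       "link_class", "n_linked_dmrs",
                                       "n_hyper", "n_hypo"])


def enrich_gene_sets(
    query: set[str],
    universe: set[str],
    collection: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment with Holm adjustment.

    P(overlap >= observed) drawing |query| genes from a universe of size M
    containing the set's members. Sets are intersected with the universe
    first; the query must be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.items():
        members = set(members) & set(universe)
        k = len(members & query)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N)) if members else 1.0
        rows.append({"set": name, "set_size": len(members), "overlap": k,
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = adjust_pvalues(table["p_value"].to_numpy(), "holm")
        table["significant"] = table["adjusted_p"] < alpha
        table = table.sort_values("adjusted_p", kind="mergesort").reset_index(drop=True)
    return table
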