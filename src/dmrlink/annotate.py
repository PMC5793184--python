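"""Genomic intervals, gene models, promoter construction and DMR annotation.

All coordinates are 0-based half-open on the forward genome axis; conversions
to 1-based conventions happen only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

FEATURE_CLASSES = (
    "TSS_flank",
    "TTS_flank",
    "exon",
    "intron",
    "UTR5",
    "UTR3",
    "CDS",
    "CGI",
    "CGI_shore",
    "repeat",
    "enhancer",
    "upstream2k",
    "downstream2k",
    "intergenic",
    "mRNA",
    "gene",
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene body with exon structure.

    ``tss`` is the first transcribed base: ``interval.start`` on "+" genes and
    ``interval.end - 1`` on "-" genes.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gene body minus exons, in forward-axis order."""
        out = []
        exons = sorted(self.exons, key=lambda e: e.start)
        cursor = self.interval.start
        for ex in exons:
            if ex.start > cursor:
                out.append(
                    GenomicInterval(self.interval.chrom, cursor, ex.start, self.strand)
                )
            cursor = max(cursor, ex.end)
        if cursor < self.interval.end:
            out.append(
                GenomicInterval(self.interval.chrom, cursor, self.interval.end, self.strand)
            )
        return out


def overlap_intervals(
    query: list[GenomicInterval], subject: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs ``(qi, si)`` where query[qi] overlaps subject[si].

    Overlap requires >= 1 bp on the same chromosome; strand is ignored.
    """
    trees: dict[str, IntervalTree] = {}
    for si, s in enumerate(subject):
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, si)
    pairs: list[tuple[int, int]] = []
    for qi, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            pairs.append((qi, hit.data))
    pairs.sort()
    return pairs


def build_promoters(
    genes: list[GeneModel],
    upstream: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """Upstream promoter interval per gene, clipped at chromosome bounds.

    "+" gene: ``[tss - upstream, tss)``; "-" gene: the mirrored upstream
    window ``[tss + 1, tss + 1 + upstream)`` on the forward axis.
    """
    promoters: dict[str, GenomicInterval] = {}
    for g in genes:
        chrom = g.interval.chrom
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + upstream
        start = max(0, start)
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        if start < end:
            promoters[g.gene_id] = GenomicInterval(chrom, start, end, g.strand)
    return promoters


def _flank(chrom: str, pos: int, half_width: int, chrom_sizes=None) -> GenomicInterval | None:
    start = max(0, pos - half_width)
    end = pos + half_width + 1
    if chrom_sizes is not None and chrom in chrom_sizes:
        end = min(end, chrom_sizes[chrom])
    return GenomicInterval(chrom, start, end) if start < end else None


def _complement(intervals: list[GenomicInterval], chrom_sizes: dict[str, int]):
    """Per-chromosome complement of a set of intervals (the intergenic space)."""
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom, size in chrom_sizes.items():
        cursor = 0
        for iv in sorted(by_chrom.get(chrom, []), key=lambda i: i.start):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < size:
            out.append(GenomicInterval(chrom, cursor, size))
    return out


def annotate_dmr_distribution(
    dmrs,
    genes: list[GeneModel],
    feature_tracks: dict[str, list[GenomicInterval]] | None = None,
    upstream: int = 2000,
    flank_half_width: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each DMR with every feature class it overlaps.

    Labelling is non-exclusive: one DMR may be exon, UTR and CGI at the same
    time. Returns ``(per_dmr_labels, distribution_table)``. The distribution
    table reports, per class, the fraction of features of that class that
    contain >= 1 DMR and the fraction of DMRs carrying the class label.
    ``dmrs`` may be DMR objects (with ``.interval``) or bare intervals.
    """
    if not genes and not feature_tracks:
        raise ValueError("empty annotation: need genes and/or feature tracks")
    feature_tracks = feature_tracks or {}
    intervals = [getattr(d, "interval", d) for d in dmrs]

    classes: dict[str, list[GenomicInterval]] = {}
    classes["gene"] = [g.interval for g in genes]
    classes["mRNA"] = [e for g in genes for e in g.exons]
    classes["exon"] = classes["mRNA"]
    classes["intron"] = [i for g in genes for i in g.introns]
    classes["UTR5"] = [u for g in genes for u in g.utr5]
    classes["UTR3"] = [u for g in genes for u in g.utr3]
    classes["CDS"] = [c for g in genes for c in g.cds]
    classes["upstream2k"] = list(build_promoters(genes, upstream, chrom_sizes).values())
    classes["downstream2k"] = [
        iv
        for g in genes
        for iv in [
            GenomicInterval(
                g.interval.chrom,
                g.interval.end if g.strand == "+" else max(0, g.interval.start - upstream),
                g.interval.end + upstream if g.strand == "+" else g.interval.start,
            )
            if (g.strand == "+" or g.interval.start > 0)
            else None
        ]
        if iv is not None
    ]
    classes["TSS_flank"] = [
        f for g in genes
        if (f := _flank(g.interval.chrom, g.tss, flank_half_width, chrom_sizes))
    ]
    classes["TTS_flank"] = [
        f for g in genes
        if (f := _flank(g.interval.chrom, g.tts, flank_half_width, chrom_sizes))
    ]
    for name, track in feature_tracks.items():
        classes[name] = list(track)
    if "CGI" in feature_tracks:
        shores = []
        for cgi in feature_tracks["CGI"]:
            left = max(0, cgi.start - 2000)
            if left < cgi.start:
                shores.append(GenomicInterval(cgi.chrom, left, cgi.start))
            shores.append(GenomicInterval(cgi.chrom, cgi.end, cgi.end + 2000))
        classes["CGI_shore"] = shores  # extension beyond the printed class list
    if chrom_sizes is not None:
        classes["intergenic"] = _complement(classes["gene"], chrom_sizes)

    labels: list[set[str]] = [set() for _ in intervals]
    frac_features: dict[str, float] = {}
    for cname, track in classes.items():
        if not track:
            frac_features[cname] = float("nan")
            continue
        pairs = overlap_intervals(intervals, track)
        hit_features = set()
        for qi, si in pairs:
            labels[qi].add(cname)
            hit_features.add(si)
        frac_features[cname] = len(hit_features) / len(track)
    if chrom_sizes is None:
        # without chromosome sizes, intergenic is "overlaps no gene-linked class"
        gene_linked = {"gene", "upstream2k", "downstream2k", "TSS_flank", "TTS_flank"}
        for lab in labels:
            if not (lab & gene_linked):
                lab.add("intergenic")

    per_dmr = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "labels": [",".join(sorted(lab)) for lab in labels],
        }
    )
    n = len(intervals)
    rows = []
    for cname in classes:
        n_dmrs = sum(cname in lab for lab in labels)
        rows.append(
            {
                "feature_class": cname,
                "n_features": len(classes[cname]),
                "frac_features_with_dmr": frac_features[cname],
                "n_dmrs": n_dmrs,
                "frac_dmrs": n_dmrs / n if n else float("nan"),
            }
        )
    return per_dmr, pd.DataFrame(rows)
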