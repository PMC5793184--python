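"""Synthetic two-condition methylome study with planted truth.

Generates every input the pipeline consumes — gene models, feature tracks,
promoter sequences, a PWM library, per-CpG bisulfite call tables for two
conditions, differential-expression tables, a five-point time-course matrix,
and a two-group validation cohort — together with a TruthSet recording what
was planted, so every downstream stage can be scored against known answers.

Noise model: each CpG carries a true methylation level; calls are
beta-binomial (binomial given a per-sample level re-draw whose spread is set
by ``dispersion``; dispersion 0 collapses to plain binomial). Coverage is
Poisson around ``coverage_mean``. CpG placement is a homogeneous Poisson
process at ``cpg_density`` per kb, densified ~4x inside planted DMRs to
emulate the CpG-island clustering where differential methylation concentrates.

All randomness flows from per-output child generators of the single config
seed, so outputs are bit-reproducible and independent of generation order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel, GenomicInterval, build_promoters
from .methio import CPG_COLUMNS

logger = logging.getLogger(__name__)

PROMOTER_LEN = 2000
_MIN_GAP = 2 * PROMOTER_LEN + 2000  # keeps neighbouring promoter windows disjoint
_DMR_DENSITY_BOOST = 6.0  # CGI-like CpG clustering inside planted DMRs
_PATTERN_CLASSES = {
    "up_linear": ("up", [0.0, 1.0, 2.0, 3.0, 4.0]),
    "up_late": ("up", [0.0, 0.0, 0.0, 4.0, 4.0]),
    "up_early": ("up", [0.0, 4.0, 4.0, 4.0, 4.0]),
    "down_linear": ("down", [4.0, 3.0, 2.0, 1.0, 0.0]),
    "down_late": ("down", [4.0, 4.0, 4.0, 0.0, 0.0]),
    "transient_up": ("transient_up", [0.0, 3.0, 4.0, 3.0, 0.0]),
}


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    cpg_density: float = 8.0  # expected CpGs per kb outside planted DMRs
    n_genes: int = 80
    n_planted_dmrs: int = 50
    dmr_length_range: tuple[int, int] = (600, 1200)
    delta_beta: float = 0.3
    baseline_beta_params: tuple[float, float] = (2.0, 2.0)
    coverage_mean: float = 30.0
    dispersion: float = 0.02
    frac_dmrs_in_promoters: float = 0.3
    frac_hyper: float = 0.55
    n_timepoints: int = 5
    n_pattern_genes_per_class: int = 100
    n_flat_genes: int = 200
    noise_sd: float = 0.2
    validation_n_per_group: int = 4
    validation_shared_frac: float = 0.5
    n_mirnas: int = 10
    n_tf_targets: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dmrs_in_promoters", "frac_hyper", "validation_shared_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.delta_beta <= 1:
            raise ValueError("delta_beta must be in [0, 1]")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one named output stream."""
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass
class PlantedDmr:
    interval: GenomicInterval
    direction: str  # hyper = condition A above condition B
    location_class: str  # promoter | body | intergenic
    gene_id: str | None = None
    mirna_id: str | None = None
    shared_with_validation: bool = False


@dataclass
class TruthSet:
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    dmr_gene_links: dict[str, str] = field(default_factory=dict)  # gene -> promoter|body|none
    planted_deg_directions: dict[str, str] = field(default_factory=dict)  # gene -> up|down|null
    planted_demirna_directions: dict[str, str] = field(default_factory=dict)
    planted_mirna_dmr: dict[str, str] = field(default_factory=dict)  # mirna -> direction
    planted_tf_edges: list[tuple[str, str, str]] = field(default_factory=list)  # (tf, gene, dir)
    planted_mirna_targets: dict[str, list[str]] = field(default_factory=dict)
    planted_pattern_labels: dict[str, str] = field(default_factory=dict)

    @property
    def shared_validation_dmrs(self) -> list[PlantedDmr]:
        return [d for d in self.planted_dmrs if d.shared_with_validation]

    def to_json(self, path: str | Path) -> None:
        def _dmr(d: PlantedDmr) -> dict:
            out = asdict(d)
            out["interval"] = [d.interval.chrom, d.interval.start, d.interval.end]
            return out

        payload = {
            "planted_dmrs": [_dmr(d) for d in self.planted_dmrs],
            "dmr_gene_links": self.dmr_gene_links,
            "planted_deg_directions": self.planted_deg_directions,
            "planted_demirna_directions": self.planted_demirna_directions,
            "planted_mirna_dmr": self.planted_mirna_dmr,
            "planted_tf_edges": self.planted_tf_edges,
            "planted_mirna_targets": self.planted_mirna_targets,
            "planted_pattern_labels": self.planted_pattern_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class Annotation:
    """Everything positional the simulator decided up front."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    promoters: dict[str, GenomicInterval]
    feature_tracks: dict[str, list[GenomicInterval]]
    promoter_seqs: dict[str, str]
    pwms: list
    mirna_loci: dict[str, GenomicInterval]
    mirna_target_table: pd.DataFrame
    ppi_table: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: TruthSet


# ---------------------------------------------------------------------------
# placement helpers

def _place_genes(config: SimulationConfig, rng: np.random.Generator,
                 chrom_sizes: dict[str, int]) -> list[GeneModel]:
    genes: list[GeneModel] = []
    chroms = list(chrom_sizes)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    gi = 0
    for chrom, n_c in zip(chroms, per_chrom):
        size = chrom_sizes[chrom]
        if n_c == 0:
            continue
        lengths = rng.integers(2000, 4501, n_c)
        needed = int(lengths.sum()) + (n_c + 1) * _MIN_GAP
        if needed > size:
            raise ValueError(
                f"genome too small: chromosome {chrom} ({size} bp) cannot hold "
                f"{n_c} genes (needs {needed} bp)"
            )
        free = size - needed
        w = rng.dirichlet(np.ones(n_c + 1))
        extras = np.floor(w * free).astype(int)
        cursor = 0
        for k in range(n_c):
            cursor += _MIN_GAP + int(extras[k])
            start, end = cursor, cursor + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(f"G{gi:04d}", chrom, start, end, strand, rng)
            genes.append(gene)
            cursor = end
            gi += 1
    return genes


def _make_gene(gene_id: str, chrom: str, start: int, end: int, strand: str,
               rng: np.random.Generator) -> GeneModel:
    n_ex = int(rng.integers(2, 5))
    k = 2 * n_ex - 1  # alternating exon/intron segments
    total = end - start
    base = 80
    leftover = total - k * base
    parts = base + rng.multinomial(leftover, np.ones(k) / k)
    bounds = np.concatenate([[0], np.cumsum(parts)]) + start
    exons = [GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand)
             for i in range(0, k, 2)]
    first = exons[0] if strand == "+" else exons[-1]
    last = exons[-1] if strand == "+" else exons[0]
    utr_len = 120
    if strand == "+":
        utr5 = [GenomicInterval(chrom, first.start, first.start + utr_len, strand)]
        utr3 = [GenomicInterval(chrom, last.end - utr_len, last.end, strand)]
    else:
        utr5 = [GenomicInterval(chrom, first.end - utr_len, first.end, strand)]
        utr3 = [GenomicInterval(chrom, last.start, last.start + utr_len, strand)]
    cds = []
    for ex in exons:
        s, e = ex.start, ex.end
        for u in utr5 + utr3:
            if u.start <= s < u.end:
                s = u.end
            if u.start < e <= u.end:
                e = u.start
        if s < e:
            cds.append(GenomicInterval(chrom, s, e, strand))
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand),
                     exons=exons, utr5=utr5, utr3=utr3, cds=cds)


def _free_intergenic(chrom_sizes, genes, promoters) -> list[GenomicInterval]:
    """Segments outside all gene bodies and promoter windows."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        occupied[g.interval.chrom].append((g.interval.start, g.interval.end))
    for p in promoters.values():
        occupied[p.chrom].append((p.start, p.end))
    out = []
    for chrom, size in chrom_sizes.items():
        cursor = 0
        for s, e in sorted(occupied[chrom]):
            if s > cursor:
                out.append(GenomicInterval(chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            out.append(GenomicInterval(chrom, cursor, size))
    return out


def _take_segment(segments: list[GenomicInterval], length: int,
                  rng: np.random.Generator) -> GenomicInterval:
    """Carve a random sub-interval of ``length`` out of the free-segment list."""
    candidates = [i for i, s in enumerate(segments) if len(s) >= length + 200]
    if not candidates:
        raise ValueError("no intergenic segment large enough for placement")
    idx = int(rng.choice(candidates))
    seg = segments.pop(idx)
    offset = int(rng.integers(100, len(seg) - length - 100 + 1))
    start = seg.start + offset
    placed = GenomicInterval(seg.chrom, start, start + length)
    if start - seg.start >= 300:
        segments.append(GenomicInterval(seg.chrom, seg.start, start))
    if seg.end - placed.end >= 300:
        segments.append(GenomicInterval(seg.chrom, placed.end, seg.end))
    return placed


# ---------------------------------------------------------------------------
# PWMs

def _make_pwms(n: int, rng: np.random.Generator, width: int = 12):
    from .networks import PWM

    pwms = []
    for i in range(n):
        consensus_idx = rng.integers(0, 4, width)
        matrix = np.full((4, width), 3.0)
        matrix[consensus_idx, np.arange(width)] = 91.0
        pwms.append(PWM(motif_id=f"SM{i + 1:04d}.1", tf_name=f"TF{i + 1}",
                        matrix=matrix.tolist()))
    return pwms


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# main operations

def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out the genome and plan all planted truth.

    Places non-overlapping gene bodies with disjoint promoter windows, plants
    DMR intervals in promoters / gene bodies / intergenic space, embeds TF
    consensus sites inside promoter DMRs of designated target genes, places
    miRNA loci (one inside a planted hypomethylated DMR), and fabricates the
    miRNA-target score, PPI and gene-set side tables.
    """
    rng = config.rng(1)
    chrom_len = config.genome_length // config.n_chromosomes
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(config.n_chromosomes)}

    genes = _place_genes(config, rng, chrom_sizes) if config.n_genes else []
    promoters = build_promoters(genes, PROMOTER_LEN, chrom_sizes)
    truth = TruthSet()
    free = _free_intergenic(chrom_sizes, genes, promoters)

    # ---- plant DMR intervals -------------------------------------------------
    n_prom = int(round(config.frac_dmrs_in_promoters * config.n_planted_dmrs))
    n_rest = config.n_planted_dmrs - n_prom
    n_body = int(round(0.6 * n_rest))
    n_inter = n_rest - n_body
    if genes:
        gene_pool = list(rng.permutation([g.gene_id for g in genes]))
    else:
        gene_pool = []
        n_prom = n_body = 0
        n_inter = config.n_planted_dmrs
    gene_by_id = {g.gene_id: g for g in genes}

    def _direction() -> str:
        return "hyper" if rng.random() < config.frac_hyper else "hypo"

    lo, hi = config.dmr_length_range
    for _ in range(n_prom):
        gid = gene_pool.pop()
        prom = promoters[gid]
        length = min(int(rng.integers(lo, hi + 1)), len(prom) - 100)
        offset = int(rng.integers(0, len(prom) - length + 1))
        iv = GenomicInterval(prom.chrom, prom.start + offset, prom.start + offset + length)
        truth.planted_dmrs.append(PlantedDmr(iv, _direction(), "promoter", gene_id=gid))
        truth.dmr_gene_links[gid] = "promoter"
    for _ in range(n_body):
        gid = gene_pool.pop()
        body = gene_by_id[gid].interval
        length = min(int(rng.integers(lo, hi + 1)), len(body) - 100)
        offset = int(rng.integers(50, len(body) - length - 50 + 1))
        iv = GenomicInterval(body.chrom, body.start + offset, body.start + offset + length)
        truth.planted_dmrs.append(PlantedDmr(iv, _direction(), "body", gene_id=gid))
        truth.dmr_gene_links[gid] = "body"
    for k in range(n_inter):
        length = int(rng.integers(lo, hi + 1))
        iv = _take_segment(free, length, rng)
        # the first intergenic DMR hosts the planted miRNA and must be hypo
        direction = "hypo" if k == 0 else _direction()
        truth.planted_dmrs.append(PlantedDmr(iv, direction, "intergenic"))
    for g in genes:
        truth.dmr_gene_links.setdefault(g.gene_id, "none")

    # validation sharing
    share = rng.random(len(truth.planted_dmrs)) < config.validation_shared_frac
    for d, s in zip(truth.planted_dmrs, share):
        d.shared_with_validation = bool(s)

    # ---- expression truth ----------------------------------------------------
    linked = [gid for gid, cls in truth.dmr_gene_links.items() if cls != "none"]
    unlinked = [gid for gid, cls in truth.dmr_gene_links.items() if cls == "none"]
    n_extra_deg = min(15, len(unlinked))
    extra = list(rng.choice(unlinked, n_extra_deg, replace=False)) if n_extra_deg else []
    for gid in linked + extra:
        truth.planted_deg_directions[gid] = "up" if rng.random() < 0.5 else "down"
    for gid in unlinked:
        truth.planted_deg_directions.setdefault(gid, "null")

    # ---- miRNA loci ----------------------------------------------------------
    mirna_loci: dict[str, GenomicInterval] = {}
    inter_dmrs = [d for d in truth.planted_dmrs if d.location_class == "intergenic"]
    for i in range(config.n_mirnas):
        mid = f"miR-sim-{i + 1:02d}"
        if i == 0 and inter_dmrs:
            host = inter_dmrs[0]
            start = host.interval.start + (len(host.interval) - 200) // 2
            mirna_loci[mid] = GenomicInterval(host.interval.chrom, start, start + 200)
            host.mirna_id = mid
            truth.planted_mirna_dmr[mid] = host.direction
            truth.planted_demirna_directions[mid] = "down"
        else:
            mirna_loci[mid] = _take_segment(free, 200, rng)
            if rng.random() < 0.4:
                truth.planted_demirna_directions[mid] = (
                    "up" if rng.random() < 0.5 else "down"
                )

    # ---- PWM library and promoter sequences ----------------------------------
    pwms = _make_pwms(5, rng)
    prom_dmr_genes = [d.gene_id for d in truth.planted_dmrs
                      if d.location_class == "promoter"]
    n_targets = min(config.n_tf_targets, len(prom_dmr_genes))
    target_genes = list(rng.choice(prom_dmr_genes, n_targets, replace=False))
    dmr_by_gene = {d.gene_id: d for d in truth.planted_dmrs if d.gene_id}
    promoter_seqs: dict[str, str] = {}
    for g in genes:
        prom = promoters[g.gene_id]
        promoter_seqs[g.gene_id] = _random_seq(rng, len(prom))
    for j, gid in enumerate(target_genes):
        pwm = pwms[j % len(pwms)]
        d = dmr_by_gene[gid]
        prom = promoters[gid]
        w = pwm.width
        rel_lo = d.interval.start - prom.start
        rel_hi = d.interval.end - prom.start - w
        offset = int(rng.integers(rel_lo, rel_hi + 1))
        seq = promoter_seqs[gid]
        promoter_seqs[gid] = seq[:offset] + pwm.consensus + seq[offset + w:]
        truth.planted_tf_edges.append((pwm.tf_name, gid, d.direction))

    # ---- feature tracks ------------------------------------------------------
    tracks: dict[str, list[GenomicInterval]] = {"CGI": [], "repeat": [], "enhancer": []}
    for gid, prom in promoters.items():
        if rng.random() < 0.4:
            tracks["CGI"].append(GenomicInterval(prom.chrom, prom.start + 500,
                                                 prom.start + 1200))
    for _ in range(30):
        try:
            tracks["repeat"].append(_take_segment(free, int(rng.integers(150, 400)), rng))
        except ValueError:
            break
    for _ in range(10):
        try:
            tracks["enhancer"].append(_take_segment(free, int(rng.integers(300, 800)), rng))
        except ValueError:
            break

    # ---- miRNA target scores, PPI, gene sets ---------------------------------
    mdeg_pool = [gid for gid in linked
                 if truth.dmr_gene_links[gid] == "body"
                 and truth.planted_deg_directions.get(gid) in ("up", "down")]
    focal_mirna = next(iter(truth.planted_mirna_dmr), None)
    rows = []
    if focal_mirna and mdeg_pool:
        n_true = min(15, len(mdeg_pool))
        true_targets = list(rng.choice(mdeg_pool, n_true, replace=False))
        truth.planted_mirna_targets[focal_mirna] = sorted(true_targets)
        for gid in true_targets:
            rows.append((focal_mirna, gid, float(rng.uniform(60, 95))))
        decoy_pool = [g.gene_id for g in genes if g.gene_id not in true_targets]
        for gid in rng.choice(decoy_pool, min(10, len(decoy_pool)), replace=False):
            rows.append((focal_mirna, str(gid), float(rng.uniform(10, 50))))
        non_mdeg = [gid for gid in decoy_pool
                    if truth.planted_deg_directions.get(gid) == "null"
                    or truth.dmr_gene_links.get(gid) != "body"]
        for gid in rng.choice(non_mdeg, min(8, len(non_mdeg)), replace=False):
            rows.append((focal_mirna, str(gid), float(rng.uniform(55, 95))))
    mirna_target_table = pd.DataFrame(rows, columns=["mirna", "gene", "score"])

    ppi_rows = []
    ppi_pool = truth.planted_mirna_targets.get(focal_mirna, []) + target_genes
    ppi_pool = sorted(set(ppi_pool))
    for _ in range(min(12, len(ppi_pool) * (len(ppi_pool) - 1) // 2)):
        pair = rng.choice(ppi_pool, 2, replace=False)
        ppi_rows.append(tuple(sorted(map(str, pair))))
    ppi_table = pd.DataFrame(sorted(set(ppi_rows)), columns=["protein_a", "protein_b"])

    gene_sets: dict[str, list[str]] = {}
    all_ids = [g.gene_id for g in genes]
    if len(all_ids) >= 20:
        chosen = list(rng.choice(all_ids, min(60, len(all_ids) - len(all_ids) % 5),
                                 replace=False))
        per = len(chosen) // 5
        for i in range(5):
            gene_sets[f"SET_{i + 1}"] = sorted(chosen[i * per:(i + 1) * per])

    return Annotation(chrom_sizes, genes, promoters, tracks, promoter_seqs, pwms,
                      mirna_loci, mirna_target_table, ppi_table, gene_sets, truth)


def _cpg_positions(config: SimulationConfig, annotation: Annotation,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Poisson CpG placement, densified inside planted DMRs."""
    rate = config.cpg_density / 1000.0
    frames = []
    for chrom, size in annotation.chrom_sizes.items():
        n_bg = rng.poisson(rate * size)
        pos = rng.integers(0, size, n_bg)
        extra = []
        for d in annotation.truth.planted_dmrs:
            if d.interval.chrom != chrom:
                continue
            n_extra = rng.poisson((_DMR_DENSITY_BOOST - 1) * rate * len(d.interval))
            extra.append(rng.integers(d.interval.start, d.interval.end, n_extra))
        if extra:
            pos = np.concatenate([pos] + extra)
        pos = np.unique(pos)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _site_means(config: SimulationConfig, annotation: Annotation, sites: pd.DataFrame,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """True per-site levels (mu_a, mu_b) with the planted DMR effects."""
    alpha, beta = config.baseline_beta_params
    mu_b = rng.beta(alpha, beta, len(sites))
    mu_b = np.clip(mu_b, 0.02, 0.98)
    mu_a = mu_b.copy()
    delta = config.delta_beta
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for d in annotation.truth.planted_dmrs:
        mask = (chroms == d.interval.chrom) & (pos >= d.interval.start) & (pos < d.interval.end)
        if not mask.any() or delta == 0:
            continue
        # anchor the low side so base +/- delta stays inside [0, 1]
        base = rng.uniform(0.1, max(0.11, 0.9 - delta), int(mask.sum()))
        jitter = rng.normal(0, 0.03, int(mask.sum()))
        low = np.clip(base + jitter, 0.02, 0.95 - delta)
        if d.direction == "hyper":
            mu_b[mask] = low
            mu_a[mask] = low + delta
        else:
            mu_a[mask] = low
            mu_b[mask] = low + delta
    n_clip = int(np.sum((mu_a < 0) | (mu_a > 1) | (mu_b < 0) | (mu_b > 1)))
    if n_clip:
        logger.warning("clipped %d site levels to [0, 1]", n_clip)
    return np.clip(mu_a, 0.0, 1.0), np.clip(mu_b, 0.0, 1.0)


def _draw_counts(mu: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    cov = rng.poisson(config.coverage_mean, len(mu))
    if config.dispersion > 0:
        k = (1.0 - config.dispersion) / config.dispersion
        a = np.clip(mu * k, 1e-6, None)
        b = np.clip((1.0 - mu) * k, 1e-6, None)
        p = rng.beta(a, b)
    else:
        p = mu
    n_meth = rng.binomial(cov, p)
    return pd.DataFrame({"n_meth": n_meth, "n_unmeth": cov - n_meth})


def _records_frame(sites: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "pos": sites["pos"].to_numpy(),
        "strand": "+",
        "context": "CpG",
        "n_meth": counts["n_meth"].to_numpy(),
        "n_unmeth": counts["n_unmeth"].to_numpy(),
    })
    covered = (df["n_meth"] + df["n_unmeth"]) > 0
    return df[covered][CPG_COLUMNS].reset_index(drop=True)


def simulate_methylome_pair(
    config: SimulationConfig, annotation: Annotation
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Per-CpG call tables for the two conditions plus the truth set.

    Outside planted DMRs both conditions share a per-site baseline level;
    inside a planted hyper DMR condition A sits ``delta_beta`` above B (hypo:
    the reverse).
    """
    rng = config.rng(2)
    sites = _cpg_positions(config, annotation, rng)
    mu_a, mu_b = _site_means(config, annotation, sites, rng)
    rec_a = _records_frame(sites, _draw_counts(mu_a, config, config.rng(3)))
    rec_b = _records_frame(sites, _draw_counts(mu_b, config, config.rng(4)))
    return rec_a, rec_b, annotation.truth


def simulate_expression_tables(
    config: SimulationConfig, truth: TruthSet, annotation: Annotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DEG and DEmiRNA tables whose loci follow the planted truth."""
    rng = config.rng(5)
    gene_by_id = {g.gene_id: g for g in annotation.genes}
    rows = []
    for gid, direction in sorted(truth.planted_deg_directions.items()):
        if direction == "null":
            continue
        iv = gene_by_id[gid].interval
        sign = 1.0 if direction == "up" else -1.0
        rows.append((gid, "gene", iv.chrom, iv.start, iv.end, direction,
                     sign * rng.uniform(1, 3), rng.uniform(1e-6, 0.01)))
    deg = pd.DataFrame(rows, columns=["id", "kind", "chrom", "start", "end",
                                      "direction", "log2fc", "fdr"])
    rows = []
    for mid, direction in sorted(truth.planted_demirna_directions.items()):
        iv = annotation.mirna_loci[mid]
        sign = 1.0 if direction == "up" else -1.0
        rows.append((mid, "miRNA", iv.chrom, iv.start, iv.end, direction,
                     sign * rng.uniform(1, 3), rng.uniform(1e-6, 0.01)))
    demirna = pd.DataFrame(rows, columns=deg.columns.tolist())
    return deg, demirna


def simulate_timecourse(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix over the deprivation time course with planted shapes.

    Six separated trajectory classes (three rising, two falling, one
    rise-then-fall) plus flat noise genes whose row SD sits below the 0.5
    minimum-SD filter.
    """
    if config.n_timepoints < 3:
        raise ValueError("need at least 3 time points")
    rng = config.rng(6)
    t = np.linspace(0, 4, config.n_timepoints)
    rows, labels, index = [], [], []
    for cname, (_pattern, template5) in _PATTERN_CLASSES.items():
        template = np.interp(t, np.linspace(0, 4, 5), template5)
        for i in range(config.n_pattern_genes_per_class):
            scale = rng.uniform(0.8, 1.25)
            intercept = rng.uniform(5, 9)
            row = intercept + scale * template + rng.normal(0, config.noise_sd,
                                                            config.n_timepoints)
            rows.append(row)
            labels.append(cname)
            index.append(f"TC_{cname}_{i:03d}")
    for i in range(config.n_flat_genes):
        rows.append(rng.uniform(5, 9) + rng.normal(0, 0.15, config.n_timepoints))
        labels.append("flat")
        index.append(f"TC_flat_{i:03d}")
    cols = [f"t{j + 1}" for j in range(config.n_timepoints)]
    matrix = pd.DataFrame(rows, index=index, columns=cols)
    return matrix, pd.Series(labels, index=index, name="pattern")


def simulate_validation_cohorts(
    config: SimulationConfig, truth: TruthSet, annotation: Annotation
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Multi-sample two-group cohort sharing a subset of the planted DMRs.

    Shared DMRs carry the same direction of effect (group 1 plays condition
    A); non-shared planted DMRs are null here. Sites and baselines are drawn
    afresh — an independent cohort does not share the discovery data's noise.
    """
    if config.validation_n_per_group < 1:
        raise ValueError("validation_n_per_group must be >= 1")
    rng = config.rng(7)
    sites = _cpg_positions(config, annotation, rng)
    alpha, beta = config.baseline_beta_params
    mu = np.clip(rng.beta(alpha, beta, len(sites)), 0.02, 0.98)
    mu_g1, mu_g2 = mu.copy(), mu.copy()
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    delta = config.delta_beta
    for d in truth.planted_dmrs:
        if not d.shared_with_validation or delta == 0:
            continue
        mask = (chroms == d.interval.chrom) & (pos >= d.interval.start) & (pos < d.interval.end)
        if not mask.any():
            continue
        low = np.clip(rng.uniform(0.1, max(0.11, 0.9 - delta), int(mask.sum())),
                      0.02, 0.95 - delta)
        if d.direction == "hyper":
            mu_g2[mask] = low
            mu_g1[mask] = low + delta
        else:
            mu_g1[mask] = low
            mu_g2[mask] = low + delta
    group1, group2 = [], []
    for s in range(config.validation_n_per_group):
        group1.append(_records_frame(sites, _draw_counts(mu_g1, config, config.rng(100 + s))))
        group2.append(_records_frame(sites, _draw_counts(mu_g2, config, config.rng(200 + s))))
    return group1, group2


def truth_dmr_frame(truth: TruthSet) -> pd.DataFrame:
    """The planted DMRs as a caller-style table (for deterministic
    integration/network checks against known truth)."""
    rows = []
    for d in truth.planted_dmrs:
        rows.append({
            "chrom": d.interval.chrom, "start": d.interval.start,
            "end": d.interval.end, "direction": d.direction,
            "fold_change": 2.0 if d.direction == "hyper" else 0.5,
            "fdr": 1e-6, "p_value": 1e-8,
            "level_a": 0.6 if d.direction == "hyper" else 0.3,
            "level_b": 0.3 if d.direction == "hyper" else 0.6,
        })
    return pd.DataFrame(rows)


def simulate_qpcr_table(config: SimulationConfig, truth: TruthSet,
                        n_replicates: int = 3) -> pd.DataFrame:
    """Ct table for a few planted DE genes, 3 replicates per group.

    A gene with planted log2 fold change L (case over control) gets case
    ΔCt shifted by -L relative to control, so 2^-ΔΔCt recovers ~2^L.
    """
    rng = config.rng(8)
    targets = [(gid, d) for gid, d in sorted(truth.planted_deg_directions.items())
               if d in ("up", "down")][:6]
    rows = []
    for gid, direction in targets:
        l2fc = rng.uniform(1, 2.5) * (1 if direction == "up" else -1)
        base_dct = rng.uniform(3, 8)
        for group, shift in (("control", 0.0), ("case", -l2fc)):
            for r in range(n_replicates):
                ct_ref = rng.uniform(14, 16)
                dct = base_dct + shift + rng.normal(0, 0.12)
                rows.append((f"{group}_{r + 1}", group, gid,
                             round(ct_ref + dct, 3), round(ct_ref, 3)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "target",
                                       "ct_target", "ct_reference"])
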