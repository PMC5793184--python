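"""End-to-end pipeline runner with a reproducibility manifest.

Stages run in dependency order: simulate (or load) inputs -> DMR calling ->
annotation -> expression integration -> network construction; the
time-course and validation arms branch off independently. Every output file
is checksummed into a manifest so re-runs with an identical configuration
can be verified byte-for-byte. The single config seed fans out to derived
per-stage seeds; no stage touches global RNG state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import annotate, integrate, io, networks, timecourse as tc, validate
from .config import PipelineConfig
from .dmr import call_dmrs, dmrs_to_frame
from .methio import methylation_summary, read_cytosine_report, write_cytosine_report
from .simulate import (
    simulate_annotation,
    simulate_expression_tables,
    simulate_methylome_pair,
    simulate_qpcr_table,
    simulate_timecourse,
    simulate_validation_cohorts,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    outdir = Path(outdir or config.paths.output_dir)
    if config.paths.input_dir is not None and not Path(config.paths.input_dir).is_dir():
        raise FileNotFoundError(f"input directory not found: {config.paths.input_dir}")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def _register(stage: str, **files: Path) -> None:
        manifest["stages"][stage] = {
            name: {"sha256": _sha256(p), "rows": _count_rows(p)}
            for name, p in sorted(files.items())
        }
        outputs.update(files)

    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)

    # ---- stage: simulate ----------------------------------------------------
    stage = "simulate"
    try:
        ann = simulate_annotation(sim_cfg)
        rec_a, rec_b, truth = simulate_methylome_pair(sim_cfg, ann)
        deg, demirna = simulate_expression_tables(sim_cfg, truth, ann)
        matrix, labels = simulate_timecourse(sim_cfg)
        truth.planted_pattern_labels = labels.to_dict()
        group1, group2 = simulate_validation_cohorts(sim_cfg, truth, ann)
        qpcr = simulate_qpcr_table(sim_cfg, truth)

        f = {}
        f["calls_a"] = outdir / "calls_condition_a.tsv"
        f["calls_b"] = outdir / "calls_condition_b.tsv"
        write_cytosine_report(rec_a, f["calls_a"])
        write_cytosine_report(rec_b, f["calls_b"])
        f["genes"] = outdir / "genes.bed12"
        io.write_bed12(ann.genes, f["genes"])
        f["promoter_seqs"] = outdir / "promoters.fa"
        io.write_fasta(ann.promoter_seqs, f["promoter_seqs"])
        f["pwms"] = outdir / "pwms.jaspar"
        io.write_jaspar_pfm(ann.pwms, f["pwms"])
        f["mirna_loci"] = outdir / "mirna_loci.bed"
        io.write_bed6(list(ann.mirna_loci.values()), f["mirna_loci"],
                      names=list(ann.mirna_loci))
        for track, ivs in ann.feature_tracks.items():
            f[f"track_{track}"] = outdir / f"track_{track}.bed"
            io.write_bed6(ivs, f[f"track_{track}"])
        f["deg"] = outdir / "deg.tsv"
        deg.to_csv(f["deg"], sep="\t", index=False)
        f["demirna"] = outdir / "demirna.tsv"
        demirna.to_csv(f["demirna"], sep="\t", index=False)
        f["mirna_targets"] = outdir / "mirna_targets.tsv"
        ann.mirna_target_table.to_csv(f["mirna_targets"], sep="\t", index=False)
        f["ppi"] = outdir / "ppi.tsv"
        ann.ppi_table.to_csv(f["ppi"], sep="\t", index=False)
        f["gene_sets"] = outdir / "gene_sets.gmt"
        io.write_gmt(ann.gene_sets, f["gene_sets"])
        f["timecourse"] = outdir / "timecourse_matrix.tsv"
        matrix.to_csv(f["timecourse"], sep="\t")
        f["qpcr"] = outdir / "qpcr_ct.tsv"
        qpcr.to_csv(f["qpcr"], sep="\t", index=False)
        f["truth"] = outdir / "truth.json"
        truth.to_json(f["truth"])
        for g, frames in (("g1", group1), ("g2", group2)):
            for i, frame in enumerate(frames):
                f[f"cohort_{g}_s{i}"] = outdir / f"cohort_{g}_sample{i}.tsv"
                write_cytosine_report(frame, f[f"cohort_{g}_s{i}"])
        _register(stage, **f)
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage named
        raise PipelineError(stage, exc) from exc

    # ---- stage: methylation summary + DMR calling ---------------------------
    stage = "dmr"
    try:
        rec_a = read_cytosine_report(outdir / "calls_condition_a.tsv")
        rec_b = read_cytosine_report(outdir / "calls_condition_b.tsv")
        summary = pd.concat([
            methylation_summary(rec_a).assign(sample="condition_a"),
            methylation_summary(rec_b).assign(sample="condition_b"),
        ])
        dmrs = call_dmrs(rec_a, rec_b, config.dmr)
        dmr_frame = dmrs_to_frame(dmrs)
        p_summary = outdir / "methylation_summary.tsv"
        summary.to_csv(p_summary, sep="\t", index=False)
        p_dmrs = outdir / "dmrs.bed"
        io.write_dmr_bed(dmr_frame, p_dmrs)
        _register(stage, summary=p_summary, dmrs=p_dmrs)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: annotate ----------------------------------------------------
    stage = "annotate"
    try:
        genes = io.read_bed12(outdir / "genes.bed12")
        per_dmr, dist = annotate.annotate_dmr_distribution(
            [annotate.GenomicInterval(r.chrom, int(r.start), int(r.end))
             for r in dmr_frame.itertuples()],
            genes, ann.feature_tracks, upstream=config.promoter_upstream,
            chrom_sizes=ann.chrom_sizes,
        )
        p_lab = outdir / "dmr_labels.tsv"
        per_dmr.to_csv(p_lab, sep="\t", index=False)
        p_dist = outdir / "dmr_distribution.tsv"
        dist.to_csv(p_dist, sep="\t", index=False)
        _register(stage, labels=p_lab, distribution=p_dist)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: integrate ---------------------------------------------------
    stage = "integrate"
    try:
        promoters = annotate.build_promoters(genes, config.promoter_upstream,
                                             ann.chrom_sizes)
        diff_all = pd.concat([deg, demirna], ignore_index=True)
        linked = integrate.flag_methylation_overlap(diff_all, dmr_frame)
        pmdegs = integrate.identify_pmdegs(deg, dmr_frame, promoters)
        mdeg_ids = sorted(e.entity_id for e in linked if e.entity_kind == "gene")
        universe = {g.gene_id for g in genes}
        enr = integrate.enrich_gene_sets(set(mdeg_ids), universe, ann.gene_sets,
                                         config.enrichment_alpha)
        p_linked = outdir / "methylation_linked.tsv"
        integrate.linked_summary(linked + pmdegs).to_csv(p_linked, sep="\t", index=False)
        p_enr = outdir / "enrichment.tsv"
        enr.to_csv(p_enr, sep="\t", index=False)
        _register(stage, linked=p_linked, enrichment=p_enr)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: networks ----------------------------------------------------
    stage = "networks"
    try:
        pmdeg_ids = sorted(e.entity_id for e in pmdegs)
        tf_edges, tf_nodes = networks.build_tf_target_network(
            pmdeg_ids, promoters, ann.promoter_seqs, ann.pwms, dmr_frame,
            deg_table=deg, ppi_table=ann.ppi_table, threshold=config.pwm_threshold,
        )
        mdemirna_ids = sorted(e.entity_id for e in linked if e.entity_kind == "miRNA")
        mir_edges, mir_nodes = networks.build_mirna_target_network(
            mdemirna_ids, ann.mirna_target_table, mdeg_ids,
            ppi_table=ann.ppi_table, min_score=config.mirna_score_min, deg_table=deg,
        )
        p_tf = outdir / "tf_network.tsv"
        networks.export_network(tf_edges, tf_nodes, p_tf, "tsv")
        p_mir = outdir / "mirna_network.tsv"
        networks.export_network(mir_edges, mir_nodes, p_mir, "tsv")
        _register(stage, tf_network=p_tf, mirna_network=p_mir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: timecourse --------------------------------------------------
    stage = "timecourse"
    try:
        z = tc.preprocess_timecourse(matrix, config.timecourse.min_sd)
        clustering = tc.fuzzy_cmeans(z, config.timecourse.c, config.timecourse.m,
                                     seed=config.seed)
        assign = tc.assignments_to_frame(
            tc.assign_and_classify(clustering, config.timecourse.membership_min))
        clustered = set(assign.loc[assign["cluster"] >= 0, "gene_id"])
        up_degs = set(deg.loc[deg["direction"] == "up", "id"])
        venn = tc.intersect_gene_sets({"clustered": clustered,
                                       "up_degs": up_degs or {"_none"}})
        p_assign = outdir / "timecourse_assignments.tsv"
        assign.to_csv(p_assign, sep="\t", index=False)
        p_venn = outdir / "timecourse_venn.tsv"
        venn.to_csv(p_venn, sep="\t", index=False)
        _register(stage, assignments=p_assign, venn=p_venn)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: validate ----------------------------------------------------
    stage = "validate"
    try:
        pooled1 = validate.pool_cohort_counts(group1)
        pooled2 = validate.pool_cohort_counts(group2)
        candidates = [annotate.GenomicInterval(r.chrom, int(r.start), int(r.end))
                      for r in dmr_frame.itertuples()]
        vcfg = config.validation
        validated = validate.call_validation_dmrs(
            pooled1, pooled2, candidates, vcfg.min_cpgs, vcfg.fdr, vcfg.fc)
        overlap = validate.cross_dataset_overlap(
            candidates, [v.interval for v in validated])
        ddct = validate.relative_expression_ddct(qpcr)
        p_val = outdir / "validated_dmrs.bed"
        with open(p_val, "w") as fh:
            for v in validated:
                fh.write(f"{v.interval.chrom}\t{v.interval.start}\t{v.interval.end}\t"
                         f"{v.direction}\t{v.n_diff_cpgs}\t{v.fold_change:.4f}\n")
        p_overlap = outdir / "cross_dataset_overlap.tsv"
        overlap.to_csv(p_overlap, sep="\t", index=False)
        p_ddct = outdir / "qpcr_results.tsv"
        ddct.to_csv(p_ddct, sep="\t", index=False)
        _register(stage, validated=p_val, overlap=p_overlap, qpcr=p_ddct)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d stages, manifest at %s",
                len(manifest["stages"]), manifest_path)
    return manifest
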