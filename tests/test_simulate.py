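"""The synthetic study generator: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from dmrlink.annotate import overlap_intervals
from dmrlink.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression_tables,
    simulate_methylome_pair,
    simulate_timecourse,
    simulate_validation_cohorts,
)


class TestDeterminism:
    def test_same_seed_reproduces_methylomes_exactly(self):
        cfg = SimulationConfig(seed=42, genome_length=200_000, n_genes=16,
                               n_planted_dmrs=10)
        a1 = simulate_annotation(cfg)
        a2 = simulate_annotation(cfg)
        r1a, r1b, _ = simulate_methylome_pair(cfg, a1)
        r2a, r2b, _ = simulate_methylome_pair(cfg, a2)
        pd.testing.assert_frame_equal(r1a, r2a)
        pd.testing.assert_frame_equal(r1b, r2b)
        assert a1.promoter_seqs == a2.promoter_seqs
        m1, l1 = simulate_timecourse(cfg)
        m2, l2 = simulate_timecourse(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(l1, l2)


class TestAnnotation:
    def test_zero_genes_gives_empty_tracks(self):
        cfg = SimulationConfig(seed=0, n_genes=0, n_planted_dmrs=5,
                               genome_length=100_000, n_tf_targets=0)
        ann = simulate_annotation(cfg)
        assert ann.genes == [] and ann.promoters == {}

    def test_genome_too_small_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation(SimulationConfig(seed=0, genome_length=50_000,
                                                 n_genes=40))

    def test_gene_bodies_do_not_overlap(self, study):
        genes = study["annotation"].genes
        ivs = [g.interval for g in genes]
        pairs = overlap_intervals(ivs, ivs)
        assert all(qi == si for qi, si in pairs)

    def test_planted_tf_target_promoter_contains_consensus(self, study):
        ann = study["annotation"]
        pwm_by_tf = {p.tf_name: p for p in ann.pwms}
        for tf, gid, _direction in study["truth"].planted_tf_edges:
            assert pwm_by_tf[tf].consensus in ann.promoter_seqs[gid]

    def test_promoter_dmrs_lie_inside_their_gene_promoter(self, study):
        ann, truth = study["annotation"], study["truth"]
        for d in truth.planted_dmrs:
            if d.location_class != "promoter":
                continue
            prom = ann.promoters[d.gene_id]
            assert prom.start <= d.interval.start < d.interval.end <= prom.end

    def test_planted_dmrs_within_chromosome_bounds(self, study):
        ann, truth = study["annotation"], study["truth"]
        for d in truth.planted_dmrs:
            assert d.interval.end <= ann.chrom_sizes[d.interval.chrom]

    def test_mirna_target_scores_straddle_fifty(self, study):
        scores = study["annotation"].mirna_target_table["score"]
        assert (scores > 50).any() and (scores < 50).any()

    def test_gene_sets_partition_a_gene_subset(self, study):
        ann = study["annotation"]
        all_members = [g for s in ann.gene_sets.values() for g in s]
        assert len(all_members) == len(set(all_members))
        gene_ids = {g.gene_id for g in ann.genes}
        assert set(all_members) <= gene_ids


class TestMethylomes:
    def test_planted_effect_size_recovered_on_average(self):
        # region-level mean difference across replicates approximates delta
        diffs = []
        for seed in range(60, 70):
            cfg = SimulationConfig(seed=seed, genome_length=200_000, n_genes=10,
                                   n_planted_dmrs=8)
            ann = simulate_annotation(cfg)
            ra, rb, truth = simulate_methylome_pair(cfg, ann)
            for d in truth.planted_dmrs:
                iv = d.interval
                for rec, sign in ((ra, 1), (rb, -1)):
                    sub = rec[(rec["chrom"] == iv.chrom) & (rec["pos"] >= iv.start)
                              & (rec["pos"] < iv.end)]
                    level = sub["n_meth"].sum() / (sub["n_meth"] + sub["n_unmeth"]).sum()
                    diffs.append(sign * level * (1 if d.direction == "hyper" else -1))
        observed = 2 * np.mean(diffs)  # mean(level_a - level_b), direction-aligned
        assert observed == pytest.approx(0.3, abs=0.03)

    def test_null_methylome_has_no_regional_difference(self):
        cfg = SimulationConfig(seed=77, delta_beta=0.0, genome_length=200_000,
                               n_genes=10, n_planted_dmrs=8)
        ann = simulate_annotation(cfg)
        ra, rb, truth = simulate_methylome_pair(cfg, ann)
        for d in truth.planted_dmrs:
            iv = d.interval
            la = ra[(ra["chrom"] == iv.chrom) & (ra["pos"] >= iv.start) & (ra["pos"] < iv.end)]
            lb = rb[(rb["chrom"] == iv.chrom) & (rb["pos"] >= iv.start) & (rb["pos"] < iv.end)]
            da = la["n_meth"].sum() / (la["n_meth"] + la["n_unmeth"]).sum()
            db = lb["n_meth"].sum() / (lb["n_meth"] + lb["n_unmeth"]).sum()
            assert abs(da - db) < 0.12

    def test_zero_dispersion_matches_binomial_variance(self):
        # variance of per-site level estimates ~ p(1-p)/n under dispersion 0
        cfg = SimulationConfig(seed=5, dispersion=0.0, genome_length=150_000,
                               n_genes=8, n_planted_dmrs=0, coverage_mean=50,
                               baseline_beta_params=(2000.0, 2000.0))
        ann = simulate_annotation(cfg)
        ra, _, _ = simulate_methylome_pair(cfg, ann)
        frac = ra["n_meth"] / (ra["n_meth"] + ra["n_unmeth"])
        n_bar = (ra["n_meth"] + ra["n_unmeth"]).mean()
        # all sites share p ~ 0.5 (tight beta), so var(frac) ~ E[p(1-p)/cov]
        assert frac.var() == pytest.approx(0.25 / n_bar, rel=0.25)


class TestExpressionTables:
    def test_all_null_directions_give_empty_deg_table(self, study):
        truth = study["truth"]
        import copy

        t = copy.deepcopy(truth)
        t.planted_deg_directions = {k: "null" for k in t.planted_deg_directions}
        t.planted_demirna_directions = {}
        deg, demirna = simulate_expression_tables(study["config"], t,
                                                  study["annotation"])
        assert deg.empty and demirna.empty

    def test_planted_mirna_is_down_and_inside_hypo_dmr(self, study):
        truth, ann = study["truth"], study["annotation"]
        demirna = study["demirna"]
        (mid, direction), = truth.planted_mirna_dmr.items()
        assert direction == "hypo"
        row = demirna[demirna["id"] == mid].iloc[0]
        assert row["direction"] == "down"
        host = next(d for d in truth.planted_dmrs if d.mirna_id == mid)
        locus = ann.mirna_loci[mid]
        assert host.interval.start <= locus.start < locus.end <= host.interval.end

    def test_same_seed_gives_identical_tables(self, study):
        deg2, demirna2 = simulate_expression_tables(
            study["config"], study["truth"], study["annotation"])
        pd.testing.assert_frame_equal(study["deg"], deg2)
        pd.testing.assert_frame_equal(study["demirna"], demirna2)


class TestTimecourseGenerator:
    def test_noiseless_monotone_class_is_strictly_monotone(self):
        cfg = SimulationConfig(seed=3, noise_sd=0.0, n_pattern_genes_per_class=5,
                               n_flat_genes=0)
        m, labels = simulate_timecourse(cfg)
        up = m[labels == "up_linear"]
        assert (up.diff(axis=1).iloc[:, 1:] > 0).all().all()

    def test_flat_rows_fall_below_sd_filter(self):
        cfg = SimulationConfig(seed=4)
        m, labels = simulate_timecourse(cfg)
        flat_sd = m[labels == "flat"].std(axis=1, ddof=1)
        assert (flat_sd < 0.5).all()

    def test_transient_class_peaks_at_interior_timepoint(self):
        cfg = SimulationConfig(seed=5, noise_sd=0.0)
        m, labels = simulate_timecourse(cfg)
        trans = m[labels == "transient_up"]
        argmax = trans.to_numpy().argmax(axis=1)
        assert ((argmax > 0) & (argmax < m.shape[1] - 1)).all()


class TestValidationCohorts:
    def test_shared_fraction_extremes(self):
        base = dict(genome_length=200_000, n_genes=10, n_planted_dmrs=8,
                    validation_n_per_group=2)
        cfg0 = SimulationConfig(seed=6, validation_shared_frac=0.0, **base)
        ann0 = simulate_annotation(cfg0)
        assert all(not d.shared_with_validation for d in ann0.truth.planted_dmrs)
        cfg1 = SimulationConfig(seed=6, validation_shared_frac=1.0, **base)
        ann1 = simulate_annotation(cfg1)
        assert all(d.shared_with_validation for d in ann1.truth.planted_dmrs)

    def test_samples_independent_given_site_means(self):
        # pairwise differences remove the shared site mean, so the noise in
        # (s1 - s2) must be uncorrelated with the noise in (s3 - s4)
        cfg = SimulationConfig(seed=8, genome_length=300_000, n_genes=10,
                               n_planted_dmrs=4, validation_n_per_group=4,
                               validation_shared_frac=0.0, dispersion=0.15)
        ann = simulate_annotation(cfg)
        g1, _ = simulate_validation_cohorts(cfg, ann.truth, ann)
        fracs = []
        merged = g1[0][["chrom", "pos"]]
        for i, s in enumerate(g1):
            s = s.assign(**{f"f{i}": s["n_meth"] / (s["n_meth"] + s["n_unmeth"])})
            merged = merged.merge(s[["chrom", "pos", f"f{i}"]], on=["chrom", "pos"])
        d12 = merged["f0"] - merged["f1"]
        d34 = merged["f2"] - merged["f3"]
        assert abs(np.corrcoef(d12, d34)[0, 1]) < 0.05
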