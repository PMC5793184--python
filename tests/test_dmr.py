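"""Window binning, region merging, testing and multiple-testing adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrlink.annotate import GenomicInterval
from dmrlink.dmr import (
    DmrConfig,
    Region,
    adjust_pvalues,
    bin_windows,
    call_dmrs,
    merge_windows,
    region_statistics,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "n_meth", "n_unmeth"])


def _region(fracs_a, fracs_b, cov=10):
    fa, fb = np.asarray(fracs_a), np.asarray(fracs_b)
    return Region(
        interval=GenomicInterval("chr1", 0, 50),
        positions=np.arange(len(fa)),
        meth_a=np.round(fa * cov).astype(int), total_a=np.full(len(fa), cov),
        meth_b=np.round(fb * cov).astype(int), total_b=np.full(len(fb), cov),
        n_windows=1,
    )


class TestBinWindows:
    def test_pooled_window_level_sums_counts(self):
        a = _records([("chr1", 10, "+", "CpG", 3, 1), ("chr1", 30, "+", "CpG", 2, 2)])
        b = _records([("chr1", 10, "+", "CpG", 1, 3), ("chr1", 30, "+", "CpG", 2, 2)])
        wins = bin_windows(a, b)
        assert len(wins) == 1
        w = wins[0]
        assert (w.interval.start, w.interval.end) == (0, 50)
        assert w.level_a == pytest.approx(5 / 8)  # 5 methylated of 8 calls
        assert w.level_b == pytest.approx(3 / 8)

    def test_window_without_shared_coverage_absent(self):
        a = _records([("chr1", 10, "+", "CpG", 3, 1), ("chr1", 60, "+", "CpG", 3, 1)])
        b = _records([("chr1", 10, "+", "CpG", 1, 3)])
        wins = bin_windows(a, b)
        assert [w.interval.start for w in wins] == [0]

    def test_empty_inputs_give_empty_list(self):
        empty = _records([])
        assert bin_windows(empty, empty) == []


class TestMergeWindows:
    def _occupied(self, starts, chrom="chr1"):
        a = _records([(chrom, s + 5, "+", "CpG", 3, 1) for s in starts])
        b = _records([(chrom, s + 5, "+", "CpG", 1, 3) for s in starts])
        return bin_windows(a, b)

    def test_adjacent_windows_merge(self):
        regions = merge_windows(self._occupied([0, 50]))
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 100)

    def test_gap_window_splits_regions(self):
        regions = merge_windows(self._occupied([0, 100]))
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 50), (100, 150)]

    def test_greedy_split_of_run_over_2kb(self):
        regions = merge_windows(self._occupied([i * 50 for i in range(45)]))
        spans = [(r.interval.start, r.interval.end) for r in regions]
        assert spans == [(0, 2000), (2000, 2250)]
        assert all(len(r.interval) <= 2000 for r in regions)


class TestRegionStatistics:
    def test_fold_change_and_levels_from_pooled_counts(self):
        la, lb, fc, _ = region_statistics(
            _region([0.8, 0.9, 0.7], [0.4, 0.5, 0.3]),
            DmrConfig(pseudocount_eps=0.0),
        )
        assert la == pytest.approx(0.8)
        assert lb == pytest.approx(0.4)
        assert fc == pytest.approx(2.0)

    def test_paired_t_matches_textbook_formula(self):
        fa = np.array([0.8, 0.7, 0.9, 0.6, 0.8])
        fb = np.array([0.4, 0.5, 0.3, 0.5, 0.2])
        *_, p = region_statistics(_region(fa, fb), DmrConfig(pseudocount_eps=0.0))
        d = fa - fb
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_identical_fractions_give_p_one(self):
        *_, p = region_statistics(_region([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]))
        assert p == 1.0

    def test_pseudocount_keeps_fold_change_finite(self):
        la, lb, fc, _ = region_statistics(
            _region([0.5, 0.5, 0.5], [0.0, 0.0, 0.0]), DmrConfig())
        assert lb == 0.0
        assert fc == pytest.approx((la + 0.01) / 0.01)


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_holm_worked_example(self):
        assert np.allclose(adjust_pvalues([0.01, 0.04], "holm"), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.3], "bh")[0] == pytest.approx(0.3)
        assert adjust_pvalues([0.3], "holm")[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    @pytest.mark.parametrize("method", ["bh", "holm"])
    def test_matches_statsmodels_on_random_vectors(self, method):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        key = {"bh": "fdr_bh", "holm": "holm"}[method]
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            ours = adjust_pvalues(p, method)
            theirs = multipletests(p, method=key)[1]
            assert np.allclose(ours, theirs, atol=1e-12)


class TestCallDmrs:
    def _planted_tables(self, n_bg=120, n_sig=12, seed=5):
        rng = np.random.default_rng(seed)
        rows_a, rows_b = [], []
        for i in range(n_bg):  # null CpGs scattered one per window pair
            pos = i * 130
            mu = rng.uniform(0.3, 0.7)
            rows_a.append(("chr1", pos, "+", "CpG", rng.binomial(30, mu), 0))
            rows_a[-1] = rows_a[-1][:4] + (rows_a[-1][4], 30 - rows_a[-1][4])
            mb = rng.binomial(30, mu)
            rows_b.append(("chr1", pos, "+", "CpG", mb, 30 - mb))
        base = 50_000
        for i in range(n_sig):  # dense hyper region
            pos = base + i * 20
            ma = rng.binomial(30, 0.8)
            mb = rng.binomial(30, 0.3)
            rows_a.append(("chr1", pos, "+", "CpG", ma, 30 - ma))
            rows_b.append(("chr1", pos, "+", "CpG", mb, 30 - mb))
        return _records(rows_a), _records(rows_b)

    def test_planted_region_called_with_hyper_direction(self):
        a, b = self._planted_tables()
        dmrs = call_dmrs(a, b)
        assert len(dmrs) >= 1
        hit = [d for d in dmrs if d.interval.start >= 49_000]
        assert hit and all(d.direction == "hyper" for d in hit)
        for d in dmrs:
            assert d.fdr < 0.05
            assert d.fold_change > 1.25 or d.fold_change < 1 / 1.25
            assert len(d.interval) <= 2000

    def test_strong_p_but_weak_fold_change_not_called(self):
        # levels 0.50 vs 0.44: consistent but under the 1.25-fold bar
        rng = np.random.default_rng(8)
        rows_a, rows_b = [], []
        for i in range(20):
            pos = i * 20
            rows_a.append(("chr1", pos, "+", "CpG", 50, 50))
            mb = rng.binomial(100, 0.44)
            rows_b.append(("chr1", pos, "+", "CpG", mb, 100 - mb))
        dmrs = call_dmrs(_records(rows_a), _records(rows_b))
        assert dmrs == []

    def test_output_invariant_to_record_order(self):
        a, b = self._planted_tables()
        shuffled_a = a.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled_b = b.sample(frac=1, random_state=2).reset_index(drop=True)
        d1 = [d.to_dict() for d in call_dmrs(a, b)]
        d2 = [d.to_dict() for d in call_dmrs(shuffled_a, shuffled_b)]
        assert d1 == d2

    def test_swapping_samples_mirrors_directions(self):
        a, b = self._planted_tables()
        cfg = DmrConfig(pseudocount_eps=0.0)
        fwd = call_dmrs(a, b, cfg)
        rev = call_dmrs(b, a, cfg)
        fwd_map = {(d.interval.start, d.interval.end): d for d in fwd}
        rev_map = {(d.interval.start, d.interval.end): d for d in rev}
        assert fwd_map.keys() == rev_map.keys()
        for key, d in fwd_map.items():
            r = rev_map[key]
            assert {d.direction, r.direction} == {"hyper", "hypo"}
            assert d.fold_change == pytest.approx(1 / r.fold_change)

    def test_empty_input_returns_empty(self):
        empty = _records([])
        assert call_dmrs(empty, empty) == []
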