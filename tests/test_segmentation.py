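"""Weighted CBS and allelic-fraction breakpoint refinement."""

import numpy as np
import pytest

from allelecn.segmentation import (
    merge_ward,
    mirrored,
    prune_breakpoints,
    segment_cbs,
    split_cnloh,
)
from conftest import make_profile, make_segment


class TestCBS:
    def test_constant_profile_is_one_segment(self):
        prof = make_profile(np.zeros(120))
        segs = segment_cbs(prof, seed=1)
        assert len(segs) == 1
        assert segs[0].num_targets == 120

    def test_single_breakpoint_recovered_within_two_targets(self, rng):
        r = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(0, 0.1, 200)
        prof = make_profile(r)
        segs = segment_cbs(prof, alpha=0.01, seed=3)
        assert len(segs) == 2
        assert abs(segs[1].tindex[0] - 100) <= 2
        assert segs[1].bp_pvalue is not None and segs[1].bp_pvalue <= 0.01

    def test_downweighted_outliers_do_not_split(self, rng):
        r = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(0, 0.1, 200)
        w = np.ones(200)
        out_idx = [10, 30, 50, 70, 90]
        r[out_idx] = 3.0
        w[out_idx] = 0.01
        prof = make_profile(r, weights=w)
        segs = segment_cbs(prof, alpha=0.01, seed=3)
        assert len(segs) == 2  # only the true breakpoint

    def test_sigma_is_member_log_ratio_sd(self, rng):
        r = rng.normal(0.3, 0.25, 150)
        prof = make_profile(r)
        segs = segment_cbs(prof, seed=1)
        assert len(segs) == 1
        assert segs[0].sigma == pytest.approx(np.std(r, ddof=1), rel=0.01)

    def test_tiling_preserved(self, rng):
        r = np.concatenate([np.zeros(70), np.full(60, 0.8), np.zeros(70)])
        r += rng.normal(0, 0.15, 200)
        prof = make_profile(r)
        segs = segment_cbs(prof, alpha=0.01, seed=5)
        all_idx = np.concatenate([s.tindex for s in segs])
        assert np.array_equal(np.sort(all_idx), np.arange(200))
        assert len(np.unique(all_idx)) == 200


class TestPrune:
    def _pair(self, p_bp, left_fracs, right_fracs):
        left = make_segment(0.0, 0.1, 50, gstart=0, size=100_000, snp_fracs=left_fracs)
        right = make_segment(
            0.1, 0.1, 50, gstart=100_000, size=100_000, snp_fracs=right_fracs,
            bp_pvalue=p_bp,
        )
        return [left, right]

    def test_borderline_breakpoint_without_af_support_merged(self, rng):
        fr = 0.48 + rng.normal(0, 0.01, 20)
        segs = self._pair(0.01, fr, 0.48 + rng.normal(0, 0.01, 20))
        merged = prune_breakpoints(segs)
        assert len(merged) == 1

    def test_significant_breakpoint_always_kept(self, rng):
        fr = 0.48 + rng.normal(0, 0.01, 20)
        segs = self._pair(0.0001, fr, fr.copy())
        assert len(prune_breakpoints(segs)) == 2

    def test_af_supported_breakpoint_kept(self, rng):
        left = 0.50 - np.abs(rng.normal(0, 0.02, 20))
        right = 0.25 + rng.normal(0, 0.02, 20)
        segs = self._pair(0.01, left, right)
        assert len(prune_breakpoints(segs)) == 2

    def test_too_few_snps_treated_as_no_support(self, rng):
        segs = self._pair(0.01, np.array([0.5, 0.48]), 0.25 + rng.normal(0, 0.02, 20))
        assert len(prune_breakpoints(segs)) == 1

    def test_snp_free_input_removes_all_borderline_breakpoints(self):
        segs = self._pair(0.05, np.empty(0), np.empty(0))
        assert len(prune_breakpoints(segs)) == 1


class TestSplitCNLOH:
    def _seg_with_fracs(self, fracs):
        seg = make_segment(0.0, 0.1, 60, gstart=0, size=600_000, snp_fracs=fracs)
        seg._target_starts = np.arange(60) * 10_000
        return seg

    def test_uniform_fractions_not_split(self, rng):
        seg = self._seg_with_fracs(np.clip(0.5 - np.abs(rng.normal(0, 0.02, 40)), 0, 0.5))
        assert len(split_cnloh([seg])) == 1

    def test_change_point_found_within_three_snps(self, rng):
        fr = np.concatenate(
            [0.5 - np.abs(rng.normal(0, 0.03, 30)), 0.2 + rng.normal(0, 0.03, 30)]
        )
        seg = self._seg_with_fracs(np.clip(fr, 0.0, 0.5))
        parts = split_cnloh([seg])
        assert len(parts) == 2
        assert abs(len(parts[0].snp_fracs) - 30) <= 3
        # copy-neutral: children keep the parent's log-ratio
        assert parts[0].r == parts[1].r == seg.r
        assert parts[0].num_targets + parts[1].num_targets == 60

    def test_too_few_snps_unchanged(self, rng):
        seg = self._seg_with_fracs(np.full(12, 0.4))
        assert len(split_cnloh([seg], min_snps=10)) == 1


class TestMergeWard:
    def test_identical_segments_share_mean(self):
        a = make_segment(0.31, 0.1, 40, chrom="chr1", snp_fracs=np.full(10, 0.5))
        b = make_segment(0.29, 0.1, 60, chrom="chr2", snp_fracs=np.full(10, 0.5))
        out = merge_ward([a, b], noise_scale=0.1)
        assert out[0].r == out[1].r
        expected = (0.31 * 40 + 0.29 * 60) / 100
        assert out[0].r == pytest.approx(expected)

    def test_distinct_level_untouched(self):
        segs = [
            make_segment(0.0, 0.1, 40, snp_fracs=np.full(8, 0.5)),
            make_segment(0.0, 0.1, 40, snp_fracs=np.full(8, 0.5)),
            make_segment(1.0, 0.1, 40, snp_fracs=np.full(8, 0.5)),
        ]
        out = merge_ward(segs, noise_scale=0.1)
        assert out[0].r == out[1].r == 0.0
        assert out[2].r == 1.0

    def test_single_segment_unchanged(self):
        seg = make_segment(0.5, 0.1, 40)
        assert merge_ward([seg]) == [seg]

    def test_boundaries_never_move(self):
        a = make_segment(0.3, 0.1, 40, gstart=0, size=100)
        b = make_segment(0.3, 0.1, 40, gstart=100, size=100)
        out = merge_ward([a, b], noise_scale=0.2)
        assert (out[0].gstart, out[0].gend) == (0, 100)
        assert (out[1].gstart, out[1].gend) == (100, 200)


def test_mirrored_fraction_folds_around_half():
    f = np.array([0.1, 0.5, 0.8, 1.0])
    assert np.allclose(mirrored(f), [0.1, 0.5, 0.2, 0.0])


def test_end_to_end_breakpoint_recovery_on_simulated_profile():
    """>=95% of true breakpoints within +/-2 targets, <=1 spurious per 1000."""
    from allelecn.simulate import simulate_coverage, simulate_genome
    from allelecn.coverage import compute_log_ratios

    found_close = 0
    n_true = 0
    n_spurious = 0
    n_targets_total = 0
    for seed in (11, 12, 13):
        truth = simulate_genome(30, 2000, purity=0.8, target_ploidy=3.0, seed=seed)
        tumor, ref, _ = simulate_coverage(truth, 100.0, noise_cv=0.1, seed=seed)
        prof = compute_log_ratios(tumor, ref, targets=truth.targets)
        prof.targets = truth.targets
        segs = segment_cbs(prof, alpha=0.01, seed=seed)
        # true breakpoints with >=0.5 copy difference at this purity
        bp_true = []
        for i in range(1, truth.n_segments):
            if abs(int(truth.C[i]) - int(truth.C[i - 1])) >= 1:
                bp_true.append(truth.seg_bounds[i])
        bp_est = [s.tindex[0] for s in segs[1:] if s.bp_pvalue is not None]
        # chromosome starts are not estimated breakpoints
        chrom_starts = set()
        ch = truth.targets["chrom"].to_numpy()
        for i in range(1, len(ch)):
            if ch[i] != ch[i - 1]:
                chrom_starts.add(i)
        bp_true = [b for b in bp_true if b not in chrom_starts]
        matched_est = set()
        for b in bp_true:
            n_true += 1
            close = [e for e in bp_est if abs(e - b) <= 2]
            if close:
                found_close += 1
                matched_est.add(close[0])
        n_spurious += sum(1 for e in bp_est if min((abs(e - b) for b in bp_true), default=99) > 2)
        n_targets_total += 2000
    assert found_close / n_true >= 0.95
    assert n_spurious / n_targets_total <= 1.5 / 1000
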