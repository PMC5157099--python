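"""Purity/ploidy likelihood, grid search and heated-Gibbs copy assignment."""

import numpy as np
import pandas as pd
import pytest

from allelecn.cnfit import (
    SUBCLONAL_COL,
    exhaustive_ml_assignment,
    expected_log_ratio,
    fit_solution,
    grid_search,
    ingest_external_segmentation,
    segment_loglik,
)
from allelecn.segmentation import SUBCLONAL
from conftest import make_segment


class TestSegmentLoglik:
    def test_pure_diploid_neutral_segment_peaks_at_zero(self):
        assert expected_log_ratio(1.0, 2, 2.0) == 0.0
        ll0 = segment_loglik(0.0, 0.1, 10, 1.0, 2, 2.0)
        for r in (0.05, -0.05, 0.2):
            assert ll0 > segment_loglik(r, 0.1, 10, 1.0, 2, 2.0)

    def test_half_purity_four_copies_mean(self):
        # (0.5*4 + 1) / (0.5*2 + 1) = 3/2
        assert expected_log_ratio(0.5, 4, 2.0) == pytest.approx(np.log2(1.5))

    def test_zero_purity_limit_hides_tumor_signal(self):
        for C in range(8):
            assert abs(expected_log_ratio(1e-9, C, 2.0)) < 1e-8

    def test_negative_copy_rejected(self):
        with pytest.raises(ValueError):
            segment_loglik(0.0, 0.1, 10, 0.5, -1, 2.0)

    def test_target_count_scales_loglik(self):
        one = segment_loglik(0.1, 0.2, 1, 0.7, 2, 2.0)
        forty = segment_loglik(0.1, 0.2, 40, 0.7, 2, 2.0)
        assert forty == pytest.approx(40 * one)


class TestGridSearch:
    def test_flat_genome_ridge_collapsed_to_single_optimum(self):
        segs = [make_segment(0.0, 0.05, 50)]
        optima = grid_search(segs)
        assert len(optima) >= 1
        # the degenerate purity ridge at D=2 collapses to one representative
        d2 = [o for o in optima if abs(o[1] - 2.0) < 0.05]
        assert len(d2) == 1

    def test_constructed_purity_ploidy_aliasing_yields_both_optima(self):
        # segments exactly consistent with (p=0.5, C={1,2,3}, D=2)
        # and with (p=0.25, C={0,2,4}, D=2)
        rs = [np.log2((0.5 * c + 1.0) / 2.0) for c in (1, 2, 3)]
        segs = [make_segment(r, 0.05, 50, gstart=i * 10**6, size=10**6) for i, r in enumerate(rs)]
        optima = grid_search(segs)
        found = {(round(p, 2), round(d, 1)) for p, d, _ in optima}
        assert any(abs(p - 0.5) <= 0.05 and abs(d - 2.0) <= 0.1 for p, d in found)
        assert any(abs(p - 0.25) <= 0.05 and abs(d - 2.0) <= 0.1 for p, d in found)

    def test_simulated_truth_among_local_optima(self):
        from allelecn.simulate import simulate_genome

        truth = simulate_genome(40, 2000, purity=0.6, target_ploidy=3.0, seed=9)
        segs = []
        for i in range(truth.n_segments):
            a, b = truth.seg_bounds[i], truth.seg_bounds[i + 1]
            r = expected_log_ratio(0.6, int(truth.C[i]), truth.ploidy)
            segs.append(make_segment(float(r), 0.3, b - a, gstart=i * 10**6, size=10**6))
        optima = grid_search(segs)
        assert any(abs(p - 0.6) <= 0.05 and abs(d - truth.ploidy) <= 0.2 for p, d, _ in optima)


def _exact_segments(purity, copies, sigma=0.05, nt=50):
    D = float(np.mean(copies))
    return [
        make_segment(
            float(expected_log_ratio(purity, c, D)), sigma, nt,
            gstart=i * 10**6, size=10**6,
        )
        for i, c in enumerate(copies)
    ], D


class TestFitSolution:
    def test_exact_three_segment_assignment_matches_brute_force(self):
        segs, D = _exact_segments(0.7, [1, 2, 3])
        sol = fit_solution(segs, 0.7, D, seed=1, optimize_purity=False, optimize_shift=False)
        assert sol.C == [1, 2, 3]
        assert sol.C == exhaustive_ml_assignment(segs, 0.7, D)
        assert sol.ploidy == pytest.approx(2.0)

    def test_flat_profile_assigns_diploid_everywhere(self):
        segs = [make_segment(0.0, 0.05, 50, gstart=i * 10**6, size=10**6) for i in range(5)]
        sol = fit_solution(segs, 0.7, 2.0, seed=2)
        assert sol.C == [2] * 5
        assert sol.ploidy == pytest.approx(2.0)

    def test_extreme_amplification_goes_subclonal(self):
        segs, D = _exact_segments(0.7, [2, 2, 2], sigma=0.05)
        segs.append(make_segment(3.5, 0.05, 50, gstart=3 * 10**6, size=10**6))  # >> C=7
        sol = fit_solution(segs, 0.7, 2.0, seed=3, optimize_purity=False)
        assert sol.C[3] == SUBCLONAL

    @pytest.mark.parametrize("seed", range(5))
    def test_gibbs_matches_exhaustive_on_random_fixtures(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_seg = int(rng.integers(3, 7))
        copies = rng.integers(0, 8, size=n_seg)
        purity = float(rng.uniform(0.3, 0.9))
        D = max(float(np.mean(copies)), 0.5)
        segs = [
            make_segment(
                float(expected_log_ratio(purity, int(c), D)) + float(rng.normal(0, 0.02)),
                0.15, int(rng.integers(20, 80)), gstart=i * 10**6, size=10**6,
            )
            for i, c in enumerate(copies)
        ]
        sol = fit_solution(segs, purity, D, seed=seed, optimize_purity=False, optimize_shift=False)
        assert sol.C == exhaustive_ml_assignment(segs, purity, D)

    def test_posteriors_normalized(self):
        segs, D = _exact_segments(0.6, [1, 2, 3, 4])
        sol = fit_solution(segs, 0.6, D, seed=4)
        assert np.allclose(sol.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_ploidy_invariant_recomputes_from_assignment(self):
        segs, D = _exact_segments(0.6, [2, 3, 4])
        sol = fit_solution(segs, 0.6, D, seed=5)
        l = np.array([s.size for s in segs], dtype=float)
        c = np.array([x for x in sol.C], dtype=float)
        assert sol.ploidy == pytest.approx(np.sum(l * c) / l.sum(), abs=1e-9)

    def test_identical_seed_identical_solution(self):
        segs, D = _exact_segments(0.55, [1, 3, 2, 4])
        a = fit_solution(segs, 0.55, D, seed=42)
        b = fit_solution(segs, 0.55, D, seed=42)
        assert a.C == b.C and a.purity == b.purity and a.shift == b.shift


class TestIngestExternalSegmentation:
    @pytest.fixture
    def intervals(self):
        from allelecn.intervals import TargetInterval

        return [TargetInterval("chr1", i * 1000, i * 1000 + 100, 0.5) for i in range(60)]

    def test_row_spanning_targets(self, intervals):
        seg_df = pd.DataFrame(
            {"ID": ["s"], "chrom": ["chr1"], "loc.start": [1], "loc.end": [50_000],
             "num.mark": [50], "seg.mean": [0.58]}
        )
        (seg,) = ingest_external_segmentation(seg_df, intervals)
        assert seg.num_targets == 50
        assert seg.r == 0.58
        assert seg.sigma == 0.1  # default when no sd column

    def test_row_without_targets_dropped(self, intervals):
        seg_df = pd.DataFrame(
            {"ID": ["s", "s"], "chrom": ["chr1", "chr2"], "loc.start": [1, 1],
             "loc.end": [10_000, 10_000], "num.mark": [10, 10], "seg.mean": [0.1, 0.2]}
        )
        segs = ingest_external_segmentation(seg_df, intervals)
        assert len(segs) == 1
        assert ingest_external_segmentation.last_dropped == 1

    def test_sd_column_used_verbatim(self, intervals):
        seg_df = pd.DataFrame(
            {"ID": ["s"], "chrom": ["chr1"], "loc.start": [1], "loc.end": [20_000],
             "num.mark": [20], "seg.mean": [0.3], "seg.sd": [0.42]}
        )
        (seg,) = ingest_external_segmentation(seg_df, intervals)
        assert seg.sigma == 0.42
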