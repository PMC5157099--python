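"""SNV likelihood model: expected fractions, priors, posteriors, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelecn.snv import (
    PriorConfig,
    SUBCLONAL_M,
    af_loglik,
    assign_minor_copy,
    classify_variants,
    expected_af,
    filter_variants,
    map_variants_to_segments,
    multiplicity_prior,
    post_optimize,
    snv_loglik,
    somatic_prior,
)
from allelecn.variants import VariantObservation, variants_frame
from conftest import make_segment


class TestExpectedAF:
    def test_pure_heterozygous_germline(self):
        assert expected_af(1.0, 2, 1, 1) == 0.5

    def test_clonal_somatic_at_65_percent(self):
        assert expected_af(0.65, 2, 1, 0) == pytest.approx(0.325, abs=1e-12)

    def test_germline_snp_in_loh(self):
        assert expected_af(0.7, 1, 1, 1) == pytest.approx(1.0 / 1.3, abs=1e-12)

    def test_no_dna_state_rejected(self):
        with pytest.raises(ValueError):
            expected_af(1.0, 0, 0, 0)


class TestAFLoglik:
    def test_beta_2_2_closed_form(self):
        # n=2, f=0.5 -> Beta(2,2); pdf(0.5) = 6 * 0.25 = 1.5
        assert af_loglik(0.5, 2, 0.5) == pytest.approx(math.log(1.5), abs=1e-9)

    def test_maximum_at_observed_fraction(self):
        f, n = 0.3, 100
        peak = af_loglik(f, n, f)
        for e in (0.2, 0.25, 0.35, 0.5):
            assert peak > af_loglik(f, n, e)

    def test_depth_capped_at_300(self):
        assert af_loglik(0.4, 500, 0.35) == af_loglik(0.4, 300, 0.35)

    def test_impossible_expectation_excluded(self):
        assert af_loglik(0.5, 100, 1.0) == -np.inf


class TestMultiplicityPrior:
    def test_balanced_diploid_germline_table(self):
        # C=2, K=1, g=1: allowed {M=1}; disallowed {0, 2} share 1-P_K
        assert multiplicity_prior(1, 1, 2, 1) == pytest.approx(0.999, abs=1e-9)
        assert multiplicity_prior(0, 1, 2, 1) == pytest.approx(0.0005, abs=1e-9)
        assert multiplicity_prior(2, 1, 2, 1) == pytest.approx(0.0005, abs=1e-9)

    def test_minor_copy_exceeding_half_is_impossible(self):
        assert multiplicity_prior(2, 2, 3, 1) == 0.0

    def test_somatic_diploid_balanced_states(self):
        # C=2, K=1, g=0: allowed {M=1 (=K=C-K, also single-chromosome), M=1/3};
        # M=2 is the one disallowed integer and carries the 1-P_K mass
        assert multiplicity_prior(1, 1, 2, 0) == pytest.approx(0.999 / 2, abs=1e-9)
        assert multiplicity_prior(SUBCLONAL_M, 1, 2, 0) == pytest.approx(0.999 / 2, abs=1e-9)
        assert multiplicity_prior(2, 1, 2, 0) == pytest.approx(0.001, abs=1e-9)

    @pytest.mark.parametrize("C", range(8))
    @pytest.mark.parametrize("g", [0, 1])
    def test_sums_to_one_over_full_support(self, C, g):
        for K in range(C // 2 + 1):
            if g == 1:
                support = [float(m) for m in range(C + 1)]
            else:
                support = [float(m) for m in range(1, C + 1)] + [SUBCLONAL_M]
            total = sum(multiplicity_prior(m, K, C, g) for m in support)
            assert total == pytest.approx(1.0, abs=1e-9), (C, K, g)


class TestSomaticPrior:
    def _v(self, **kw):
        base = dict(chrom="chr1", pos=100, ref="A", alt="T", f=0.3, n=100)
        base.update(kw)
        return VariantObservation(**base)

    @pytest.mark.parametrize(
        "kw,matched,expected",
        [
            (dict(cosmic_count=5), False, 0.95),
            (dict(in_dbsnp=True), False, 0.0005),
            (dict(in_dbsnp=True, cosmic_count=5), False, 0.01),
            (dict(), False, 0.5),
            (dict(matched_status="somatic"), True, 0.999),
            (dict(matched_status="germline"), True, 0.0001),
        ],
    )
    def test_prior_table(self, kw, matched, expected):
        assert somatic_prior(self._v(**kw), matched) == expected

    def test_cosmic_evidence_never_decreases_somatic_posterior(self):
        post = np.zeros(9)
        post[2] = 1.0
        p_som = []
        for cnt in (0, 3):
            vdf = variants_frame([self._v(f=0.33, n=200, cosmic_count=cnt)])
            tbl = classify_variants(vdf, np.array([0]), post[None, :], 0.65)
            p_som.append(tbl["posterior_somatic"].iloc[0])
        assert p_som[1] >= p_som[0]


def _oracle_posterior(f, n, p, pC, prior_som, in_dbsnp, priors=None):
    """Slow reference enumeration over (C, K, M, g) states for one variant."""
    pr = priors or PriorConfig()
    n = min(n, pr.max_depth)
    a, b = n * f + 1, n * (1 - f) + 1
    weights = {}
    for C in range(8):
        if pC[C] == 0:
            continue
        for K in range(C // 2 + 1):
            pk = 1.0 / (C + 1)
            for g in (0, 1):
                support = (
                    [float(m) for m in range(C + 1)]
                    if g
                    else [float(m) for m in range(1, C + 1)] + [SUBCLONAL_M]
                )
                pg = (1 - prior_som) if g else prior_som
                for M in support:
                    pm = multiplicity_prior(M, K, C, g, pr.p_k)
                    if pm == 0:
                        continue
                    ef = (p * M + g * (1 - p)) / (p * C + 2 * (1 - p))
                    like = stats.beta.pdf(ef, a, b)
                    weights[(g, M, C)] = weights.get((g, M, C), 0.0) + pC[C] * pk * pm * pg * like
    if in_dbsnp:
        for name, ef_fn in (
            ("CONTAMINATION_REF", lambda C: (p * C + 2 * (1 - p - pr.contamination_rate)) / (p * C + 2 * (1 - p))),
            ("CONTAMINATION_ALT", lambda C: pr.contamination_rate / (p * C + 2 * (1 - p))),
        ):
            w = sum(pC[C] * stats.beta.pdf(min(max(ef_fn(C), 0), 1), a, b) for C in range(8))
            weights[name] = w * pr.contamination_prior
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


class TestVariantPosterior:
    def _classify_one(self, f, n, p, C, in_dbsnp=False, cosmic=0):
        post = np.zeros(9)
        post[C] = 1.0
        v = VariantObservation("chr1", 100, "A", "T", f, n, in_dbsnp=in_dbsnp, cosmic_count=cosmic)
        return classify_variants(variants_frame([v]), np.array([0]), post[None, :], p)

    def test_novel_variant_at_somatic_fraction_called_somatic(self):
        tbl = self._classify_one(0.33, 200, 0.65, 2)
        row = tbl.iloc[0]
        assert row["ML.SOMATIC"]
        assert row["ML.M"] == 1.0
        assert row["CELLFRACTION"] == pytest.approx(1.0, abs=0.05)

    def test_dbsnp_variant_at_half_called_germline(self):
        row = self._classify_one(0.50, 200, 0.65, 2, in_dbsnp=True).iloc[0]
        assert not row["ML.SOMATIC"]
        assert row["ML.M"] == 1.0

    @pytest.mark.parametrize(
        "f,n,p,C,in_dbsnp",
        [(0.33, 200, 0.65, 2, False), (0.50, 200, 0.65, 2, True), (0.75, 150, 0.7, 3, True)],
    )
    def test_matches_enumeration_oracle(self, f, n, p, C, in_dbsnp):
        pC = np.zeros(8)
        pC[C] = 1.0
        prior = 0.0005 if in_dbsnp else 0.5
        oracle = _oracle_posterior(f, n, p, pC, prior, in_dbsnp)
        tbl = self._classify_one(f, n, p, C, in_dbsnp=in_dbsnp)
        row = tbl.iloc[0]
        p_som_oracle = sum(v for k, v in oracle.items() if isinstance(k, tuple) and k[0] == 0)
        assert row["posterior_somatic"] == pytest.approx(p_som_oracle, abs=1e-6)
        ml_oracle = max(oracle, key=oracle.get)
        if isinstance(ml_oracle, tuple):
            assert row["ML.STATE"] == str((ml_oracle[0], ml_oracle[1], ml_oracle[2]))

    def test_posterior_rows_normalized(self):
        post = np.zeros((1, 9))
        post[0, :8] = 1 / 8
        vs = [
            VariantObservation("chr1", 100, "A", "T", 0.4, 80, in_dbsnp=True),
            VariantObservation("chr1", 200, "A", "T", 0.9, 120),
        ]
        _, pmat, _ = classify_variants(
            variants_frame(vs), np.array([0, 0]), post, 0.6, return_posterior=True
        )
        assert np.allclose(np.nansum(pmat, axis=1), 1.0, atol=1e-9)

    def test_contamination_spot_values(self):
        pr = PriorConfig()
        p, C = 0.6, 2
        e7 = (p * C + 2 * (1 - p - pr.contamination_rate)) / (p * C + 2 * (1 - p))
        e8 = pr.contamination_rate / (p * C + 2 * (1 - p))
        assert e7 == pytest.approx(0.99, abs=1e-12)
        assert e8 == pytest.approx(0.005, abs=1e-12)

    def test_contamination_states_admitted_only_for_dbsnp(self):
        # a fraction near 1 at modest purity fits the contamination-ref state
        row_db = self._classify_one(0.98, 200, 0.6, 2, in_dbsnp=True).iloc[0]
        row_novel = self._classify_one(0.98, 200, 0.6, 2, in_dbsnp=False).iloc[0]
        assert row_db["ML.STATE"] == "CONTAMINATION_REF"
        assert row_novel["ML.STATE"] != "CONTAMINATION_REF"

    def test_high_purity_mode_adds_homozygous_state(self):
        # all-alt reads at high purity in a balanced segment: no heterozygous
        # state fits, the homozygous-germline state catches the SNP
        post = np.zeros(9)
        post[2] = 1.0
        v = VariantObservation("chr1", 100, "A", "T", 1.0, 300, in_dbsnp=False)
        tbl = classify_variants(
            variants_frame([v]), np.array([0]), post[None, :], 0.95, high_purity_mode=True
        )
        assert tbl.iloc[0]["ML.STATE"] == "GERMLINE_HOMOZYGOUS"
        # without high-purity mode the state does not exist
        tbl2 = classify_variants(
            variants_frame([v]), np.array([0]), post[None, :], 0.95, high_purity_mode=False
        )
        assert tbl2.iloc[0]["ML.STATE"] != "GERMLINE_HOMOZYGOUS"

    def test_variant_outside_segments_flagged(self):
        v = VariantObservation("chr1", 100, "A", "T", 0.4, 80)
        tbl = classify_variants(
            variants_frame([v]), np.array([-1]), np.zeros((1, 9)), 0.6
        )
        assert tbl.iloc[0]["FLAG.OUTSIDE_SEGMENTS"]

    def test_cellfraction_self_consistency(self):
        # f at the clonal somatic expectation gives h = 1 exactly
        f = expected_af(0.65, 2, 1, 0)
        assert (f / 1.0) * (0.65 * 2 + 2 * 0.35) / 0.65 == pytest.approx(1.0, abs=1e-12)


class TestFilterVariants:
    def _vdf(self, **kw):
        base = dict(chrom="chr1", pos=100, ref="A", alt="T", f=0.5, n=100)
        base.update(kw)
        return variants_frame([VariantObservation(**base)])

    def test_matched_homozygous_normal_removed(self):
        vdf = self._vdf(normal_f=1.0, normal_n=80)
        kept, flags = filter_variants(vdf, matched=True)
        assert len(kept) == 0
        assert flags["removed_homozygous"].iloc[0]

    def test_balanced_normal_retained(self):
        kept, _ = filter_variants(self._vdf(normal_f=0.5, normal_n=100), matched=True)
        assert len(kept) == 1

    def test_mapping_biased_normal_removed(self):
        kept, flags = filter_variants(self._vdf(normal_f=0.30, normal_n=300), matched=True)
        assert len(kept) == 0
        assert flags["removed_mapping_bias"].iloc[0]

    def test_unmatched_near_homozygous_removed_unless_high_purity(self):
        vdf = self._vdf(f=0.97)
        kept, _ = filter_variants(vdf, matched=False)
        assert len(kept) == 0
        kept_hp, _ = filter_variants(vdf, matched=False, high_purity_mode=True)
        assert len(kept_hp) == 1


class TestSNVLoglikAndLOH:
    def _tables(self, p=0.6):
        post = np.zeros((1, 9))
        post[0, 2] = 1.0
        vs = [VariantObservation("chr1", 100 + i, "A", "T", 0.3, 100) for i in range(4)]
        vdf = variants_frame(vs)
        return vdf, classify_variants(vdf, np.zeros(4, dtype=int), post, p)

    def test_loglik_is_sum_of_best_states(self):
        _, tbl = self._tables()
        assert snv_loglik(tbl) == pytest.approx(tbl["max_loglik"].sum())

    def test_duplicating_variants_doubles_loglik(self):
        _, tbl = self._tables()
        doubled = pd.concat([tbl, tbl], ignore_index=True)
        assert snv_loglik(doubled) == pytest.approx(2 * snv_loglik(tbl))

    def _loh_fixture(self, K, p=0.6, n_snps=30, seed=5):
        """Segment with C=2 and germline SNPs phased at minor copy K."""
        from allelecn.cnfit import Solution

        rng = np.random.default_rng(seed)
        seg = make_segment(0.0, 0.1, 50, gstart=0, size=10**6)
        vs = []
        for i in range(n_snps):
            M = K if rng.random() < 0.5 else 2 - K
            ef = expected_af(p, 2, M, 1)
            n = 100
            f = rng.binomial(n, ef) / n
            vs.append(
                VariantObservation("chr1", 1000 + i * 100, "A", "T", float(f), n, in_dbsnp=True)
            )
        vdf = variants_frame(vs)
        post = np.zeros((1, 9))
        post[0, 2] = 1.0
        sol = Solution(
            purity=p, ploidy=2.0, C=[2], posteriors=post, shift=0.0, cn_loglik=0.0
        )
        seg_index = map_variants_to_segments(vdf, [seg])
        assign_minor_copy([seg], sol, vdf, seg_index)
        return seg

    def test_copy_neutral_loh_detected(self):
        seg = self._loh_fixture(K=0)
        assert seg.K == 0 and seg.loh

    def test_balanced_diploid_not_loh(self):
        seg = self._loh_fixture(K=1)
        assert seg.K == 1 and not seg.loh


class TestPostOptimize:
    def test_post_optimization_moves_purity_toward_truth(self):
        """Variants simulated at p=0.5 pull a perturbed 0.55 start back."""
        from allelecn.cnfit import Solution

        from allelecn.cnfit import expected_log_ratio

        rng = np.random.default_rng(11)
        true_p = 0.5
        copies = [2, 2, 2, 3]
        D = 2.25
        segs = [
            make_segment(
                float(expected_log_ratio(true_p, c, D)), 0.2, 50,
                gstart=i * 10**6, size=10**6,
            )
            for i, c in enumerate(copies)
        ]
        vs = []
        for i in range(75):  # clonal somatic in diploid segments
            ef = expected_af(true_p, 2, 1, 0)
            n = int(rng.poisson(100))
            f = rng.binomial(n, ef) / n
            vs.append(VariantObservation("chr1", 1000 + i * 100, "A", "T", float(f), n))
        for i in range(40):  # balanced germline SNPs (purity-uninformative)
            n = int(rng.poisson(100))
            f = rng.binomial(n, 0.5) / n
            vs.append(
                VariantObservation(
                    "chr1", 1_200_000 + i * 100, "A", "T", float(f), n, in_dbsnp=True
                )
            )
        for i in range(35):  # germline SNPs in the unbalanced C=3 segment
            M = 1 if rng.random() < 0.5 else 2
            ef = expected_af(true_p, 3, M, 1)
            n = int(rng.poisson(100))
            f = rng.binomial(n, ef) / n
            vs.append(
                VariantObservation(
                    "chr1", 3_000_000 + i * 100, "A", "T", float(f), n, in_dbsnp=True
                )
            )
        vdf = variants_frame(vs)
        post = np.zeros((4, 9))
        for i, c in enumerate(copies):
            post[i, c] = 1.0
        sol = Solution(
            purity=0.55, ploidy=D, C=copies, posteriors=post, shift=0.0, cn_loglik=0.0
        )
        seg_index = map_variants_to_segments(vdf, segs)

        def total_at(p):
            tbl = classify_variants(vdf, seg_index, post, p)
            return float(np.nansum(tbl["evidence"].to_numpy()))

        out = post_optimize(sol, segs, vdf, seg_index)
        assert abs(out.purity - true_p) <= abs(0.55 - true_p)
        assert total_at(true_p) >= total_at(0.55)
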