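"""replicate_concordance: mismatch classes, curves, correlations, STR, overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsecellqc import (
    SitePairClass,
    STRStatus,
    UndefinedStatisticError,
    classify_site_pair,
    compare_str,
    fit_exponential,
    genotype_likelihood_correlation,
    mismatch_curve,
    mismatch_fraction,
    variant_set_overlap,
)
from sparsecellqc.synthetic_data import STRObservation

from conftest import make_call, make_replicate


class TestClassifySitePair:
    def test_same_het_call_is_concordant(self):
        a = make_call(gt="het", alt="G")
        assert classify_site_pair(a, make_call(gt="het", alt="G")) is SitePairClass.CONCORDANT

    def test_same_hom_alt_call_is_concordant(self):
        a = make_call(gt="hom_alt", alt="G", ad=(0, 30))
        b = make_call(gt="hom_alt", alt="G", ad=(1, 29))
        assert classify_site_pair(a, b) is SitePairClass.CONCORDANT

    @pytest.mark.parametrize("direction", ["ab", "ba"])
    def test_het_versus_hom_alt_is_loh(self, direction):
        het = make_call(gt="het", alt="G")
        hom = make_call(gt="hom_alt", alt="G", ad=(0, 30))
        pair = (het, hom) if direction == "ab" else (hom, het)
        assert classify_site_pair(*pair) is SitePairClass.LOH

    def test_different_alt_allele_is_allele_change(self):
        a = make_call(gt="het", alt="G")
        b = make_call(gt="het", alt="T")
        assert classify_site_pair(a, b) is SitePairClass.ALLELE_CHANGE

    def test_one_sided_site_is_total_dropout(self):
        a = make_call(gt="het", alt="G")
        assert classify_site_pair(a, None) is SitePairClass.TOTAL_DROPOUT
        assert classify_site_pair(None, a) is SitePairClass.TOTAL_DROPOUT

    def test_both_absent_rejected(self):
        with pytest.raises(ValueError):
            classify_site_pair(None, None)


class TestMismatchFraction:
    def test_identical_replicates_have_zero_mismatch(self):
        calls = [make_call(pos=p) for p in (10, 20, 30)]
        s = mismatch_fraction(make_replicate(calls), make_replicate(calls))
        assert s.mismatch_fraction == 0.0
        assert s.counts[SitePairClass.CONCORDANT] == 3

    def test_four_site_toy_enumeration(self):
        # 2 concordant, 1 loh, 1 total dropout -> fraction 0.5
        a = make_replicate(
            [
                make_call(pos=10, gt="het"),
                make_call(pos=20, gt="hom_alt", ad=(0, 30)),
                make_call(pos=30, gt="het"),
                make_call(pos=40, gt="het"),
            ]
        )
        b = make_replicate(
            [
                make_call(pos=10, gt="het"),
                make_call(pos=20, gt="hom_alt", ad=(0, 28), dp=30),
                make_call(pos=30, gt="hom_alt", ad=(1, 29)),
            ]
        )
        s = mismatch_fraction(a, b)
        assert s.n_sites_considered == 4
        assert s.mismatch_fraction == pytest.approx(0.5)
        assert s.counts[SitePairClass.LOH] == 1
        assert s.counts[SitePairClass.TOTAL_DROPOUT] == 1

    def test_empty_against_three_sites_is_full_dropout(self):
        b = make_replicate(make_call(pos=p) for p in (1, 2, 3))
        s = mismatch_fraction(make_replicate([]), b)
        assert s.mismatch_fraction == 1.0
        assert s.counts[SitePairClass.TOTAL_DROPOUT] == 3
        assert s.dropout_only_b == 3

    def test_empty_universe_is_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            mismatch_fraction(make_replicate([]), make_replicate([]))

    def test_indels_excluded_from_snv_statistics(self):
        a = make_replicate([make_call(pos=10, ref="A", alt="AT", gt="het")])
        b = make_replicate([make_call(pos=10, ref="A", alt="AT", gt="het")])
        with pytest.raises(UndefinedStatisticError):
            mismatch_fraction(a, b)  # universe empty once indels drop out
        assert mismatch_fraction(a, b, snv_only=False).mismatch_fraction == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 50), st.booleans(), st.booleans()),
                    min_size=1, max_size=25, unique_by=lambda t: t[0]))
    def test_symmetry_and_count_conservation(self, spec):
        """f(a,b) = f(b,a) and class counts sum to |union of sites|."""
        calls_a = [make_call(pos=p, gt="het") for p, in_a, _ in spec if in_a]
        calls_b = [make_call(pos=p, gt="hom_alt", ad=(0, 30)) for p, _, in_b in spec if in_b]
        if not (calls_a or calls_b):
            return
        a, b = make_replicate(calls_a), make_replicate(calls_b)
        sab = mismatch_fraction(a, b)
        sba = mismatch_fraction(b, a)
        assert sab.mismatch_fraction == sba.mismatch_fraction
        assert sum(sab.counts.values()) == sab.n_sites_considered


class TestMismatchCurve:
    def test_single_pair_per_count_reproduces_fractions(self):
        a1 = make_replicate([make_call(pos=1)], cell_count=1)
        b1 = make_replicate([make_call(pos=2)], cell_count=1)  # disjoint -> 1.0
        a5 = make_replicate([make_call(pos=1)], cell_count=5)
        b5 = make_replicate([make_call(pos=1)], cell_count=5)  # identical -> 0.0
        curve = mismatch_curve([(a1, b1), (a5, b5)])
        assert curve == [(1, 1.0), (5, 0.0)]

    def test_pairs_at_same_count_are_averaged(self):
        mk = lambda sites, cc: make_replicate([make_call(pos=p) for p in sites], cell_count=cc)
        pairs = [
            (mk([1], 2), mk([1], 2)),  # 0.0
            (mk([1], 2), mk([2], 2)),  # 1.0
            (mk([1], 9), mk([1], 9)),
        ]
        curve = mismatch_curve(pairs)
        assert curve[0] == (2, 0.5)

    def test_mismatched_cell_counts_rejected(self):
        a = make_replicate([make_call()], cell_count=1)
        b = make_replicate([make_call()], cell_count=5)
        with pytest.raises(ValueError):
            mismatch_curve([(a, b)])


class TestCodingRegionRestriction:
    def test_restriction_never_increases_mismatch_with_offtarget_artifacts(self, genome):
        """Spurious amplification-artifact calls land off-target and are
        replicate-private, so restricting to coding regions can only
        remove discordant sites."""
        from sparsecellqc import AmplificationModel, restrict_to_regions, simulate_assay

        model = AmplificationModel(false_positive_rate=0.1)
        regions = genome.coding_regions()
        for seed in range(5):
            a = simulate_assay(genome, model, 2, seed=3000 + 2 * seed)
            b = simulate_assay(genome, model, 2, seed=3001 + 2 * seed, replicate_index=1)
            full = mismatch_fraction(a, b).mismatch_fraction
            coding = mismatch_fraction(
                restrict_to_regions(a, regions), restrict_to_regions(b, regions)
            ).mismatch_fraction
            assert coding <= full


class TestExponentialFit:
    def test_noiseless_parameter_recovery(self):
        a, b, c = 0.4, 0.5, 0.1
        xs = [1, 2, 5, 25, 50]
        pts = [(x, a * np.exp(-b * x) + c) for x in xs]
        fit = fit_exponential(pts)
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        assert fit.decay_rate == pytest.approx(b, abs=1e-6)
        assert fit.floor == pytest.approx(c, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_points_collapse_to_floor(self):
        fit = fit_exponential([(x, 0.25) for x in (1, 5, 10, 50)])
        assert fit.predict(100) == pytest.approx(0.25, abs=1e-6)
        assert fit.amplitude * np.exp(-fit.decay_rate) == pytest.approx(0.0, abs=1e-6)

    def test_fitted_curve_is_non_increasing(self):
        fit = fit_exponential([(1, 0.5), (5, 0.2), (10, 0.15), (50, 0.1)])
        xs = np.linspace(0, 60, 200)
        ys = fit.predict(xs)
        assert np.all(np.diff(ys) <= 1e-12)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_exponential([(1, 0.5), (2, 0.3)])


class TestGenotypeLikelihoodCorrelation:
    @staticmethod
    def _rep_with_pls(het_pls, **kwargs):
        # hom-alt calls let the het PL component vary freely while min(PL)=0
        calls = [
            make_call(pos=10 * (i + 1), gt="hom_alt", ad=(0, 30), pl=(60, int(p), 0))
            for i, p in enumerate(het_pls)
        ]
        return make_replicate(calls, **kwargs)

    def test_identical_pl_vectors_give_rho_one(self):
        a = self._rep_with_pls([10, 20, 30, 40])
        b = self._rep_with_pls([10, 20, 30, 40])
        rho, n = genotype_likelihood_correlation(a, b)
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_reversed_ranks_give_rho_minus_one(self):
        a = self._rep_with_pls([10, 20, 30, 40])
        b = self._rep_with_pls([40, 30, 20, 10])
        rho, _ = genotype_likelihood_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_independent_likelihoods_are_uncorrelated(self, rng):
        pls_a = rng.integers(1, 500, size=1000)
        pls_b = rng.integers(1, 500, size=1000)
        rho, n = genotype_likelihood_correlation(
            self._rep_with_pls(pls_a), self._rep_with_pls(pls_b)
        )
        assert n == 1000
        assert abs(rho) < 0.1

    def test_fewer_than_three_shared_sites_is_signalled(self):
        a = self._rep_with_pls([10, 20])
        b = self._rep_with_pls([10, 20])
        with pytest.raises(UndefinedStatisticError):
            genotype_likelihood_correlation(a, b)


class TestCompareSTR:
    REF = [
        STRObservation("L1", 10, 12, 1000, 1000),
        STRObservation("L2", 8, 11, 1000, 1000),
        STRObservation("L3", 9, 9, 1000, 0),  # homozygous
    ]

    def test_balanced_panel_has_no_affected_loci(self):
        obs = [
            STRObservation("L1", 10, 12, 900, 1100),
            STRObservation("L2", 8, 11, 1000, 800),
            STRObservation("L3", 9, 9, 950, 0),
        ]
        _, affected = compare_str(self.REF, obs)
        assert affected == 0

    def test_single_missing_peak_is_complete_loh(self):
        obs = [
            STRObservation("L1", 10, 12, 1000, 0),
            STRObservation("L2", 8, 11, 1000, 900),
            STRObservation("L3", 9, 9, 950, 0),
        ]
        comparisons, affected = compare_str(self.REF, obs)
        assert affected == 1
        assert comparisons[0].status is STRStatus.COMPLETE_LOH

    def test_peak_imbalance_beyond_ratio_threshold_is_partial_dropout(self):
        obs = [
            STRObservation("L1", 10, 12, 1000, 200),  # ratio 5 > 3
            STRObservation("L2", 8, 11, 1000, 900),
            STRObservation("L3", 9, 9, 950, 0),
        ]
        comparisons, _ = compare_str(self.REF, obs, imbalance_ratio_threshold=3)
        assert comparisons[0].status is STRStatus.PARTIAL_DROPOUT
        # ratio 5 is fine at a laxer threshold
        comparisons, _ = compare_str(self.REF, obs, imbalance_ratio_threshold=6)
        assert comparisons[0].status is STRStatus.CONCORDANT

    def test_both_peaks_absent_is_full_dropout(self):
        obs = [
            STRObservation("L1", 10, 12, 0, 0),
            STRObservation("L2", 8, 11, 1000, 900),
            STRObservation("L3", 9, 9, 0, 0),
        ]
        comparisons, affected = compare_str(self.REF, obs)
        assert comparisons[0].status is STRStatus.FULL_DROPOUT
        assert comparisons[2].status is STRStatus.FULL_DROPOUT
        assert affected == 2

    def test_locus_panel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="panels differ"):
            compare_str(self.REF, self.REF[:2])


class TestVariantSetOverlap:
    def test_reference_subset_of_replicate_is_full_overlap(self):
        rep = make_replicate(make_call(pos=p) for p in range(1, 11))
        res = variant_set_overlap(rep, [("chr1", p, "A", "G") for p in (2, 4, 6)])
        assert res.overlap_fraction == 1.0

    def test_disjoint_sets_have_zero_overlap(self):
        rep = make_replicate([make_call(pos=1)])
        res = variant_set_overlap(rep, [("chr2", 99, "C", "T")])
        assert res.overlap_fraction == 0.0

    def test_six_of_ten_reference_variants_present(self):
        rep = make_replicate(make_call(pos=p) for p in range(1, 7))
        ref = [("chr1", p, "A", "G") for p in range(1, 11)]
        res = variant_set_overlap(rep, ref)
        assert res.overlap_fraction == pytest.approx(0.6)
        assert res.intersection <= min(res.reference_size, len(rep))

    def test_empty_reference_is_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            variant_set_overlap(make_replicate([make_call()]), [])
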