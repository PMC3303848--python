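import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnbmla.qc_frequentist import (
    ContingencyTable2x2,
    allele_association_test,
    bonferroni_threshold,
    display_significance,
    genotype_association_test,
    haplotype_or_from_frequencies,
    hwe_test,
    logistic_interaction_fit,
    qc_filter,
)
from helpers import make_dataset


class TestHWE:
    def test_exact_hardy_weinberg_proportions_give_zero(self):
        res = hwe_test(49, 42, 9)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_missing_heterozygotes_flagged_as_deviation(self):
        assert hwe_test(50, 0, 50).p < 0.005

    def test_hand_computed_statistic(self):
        # p-hat = 0.5 -> expected 25/50/25 -> chi2 = 1 + 2 + 1 = 4
        res = hwe_test(30, 40, 30)
        assert res.chi2 == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_monomorphic_input_is_a_defined_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test(100, 0, 0)

    @given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_allele_relabeling_invariance(self, a, h, b):
        assert hwe_test(a, h, b).chi2 == pytest.approx(hwe_test(b, h, a).chi2)


class TestAlleleAssociation:
    def test_symmetric_table_is_null(self):
        res = allele_association_test(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0)

    def test_cross_product_odds_ratio(self):
        res = allele_association_test(ContingencyTable2x2(10, 90, 20, 80))
        assert res.odds_ratio == pytest.approx(800 / 1800)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_zero_cell_gets_haldane_correction_and_flag(self):
        res = allele_association_test(ContingencyTable2x2(0, 10, 10, 10))
        assert res.corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    @given(st.tuples(*[st.integers(1, 100)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_exposure_swap_inverts_odds_ratio(self, t):
        a, b, c, d = t
        fwd = allele_association_test(ContingencyTable2x2(a, b, c, d))
        swp = allele_association_test(ContingencyTable2x2(b, a, d, c))
        assert fwd.odds_ratio == pytest.approx(1.0 / swp.odds_ratio)
        assert fwd.chi2 == pytest.approx(swp.chi2)


class TestGenotypeAssociation:
    def test_identical_distributions_are_null(self):
        res = genotype_association_test([30, 40, 30], [60, 80, 60])
        assert res.chi2 == pytest.approx(0.0)
        assert res.df == 2

    def test_recessive_fixture_favors_recessive_model(self):
        # minor homozygotes enriched in cases only
        res = genotype_association_test([25, 40, 35], [30, 50, 20])
        assert res.recessive is not None
        assert res.recessive.p < res.p

    def test_absent_class_collapses_to_one_df(self):
        with pytest.warns(UserWarning, match="collapsing"):
            res = genotype_association_test([30, 70, 0], [50, 50, 0])
        assert res.df == 1 and res.collapsed


class TestQCFilter:
    def build(self):
        rng = np.random.default_rng(5)
        n = 200
        cols = {}
        for i in range(7):  # clean SNPs in good HWE (maf 0.3)
            g = rng.binomial(1, 0.3, n) + rng.binomial(1, 0.3, n)
            cols[f"ok{i}"] = g
        cols["mono"] = np.zeros(n, dtype=int)
        hwe_bad = np.where(rng.random(n) < 0.5, 0, 2)  # no heterozygotes
        cols["hwe_bad"] = hwe_bad
        cols["lowcall"] = rng.binomial(2, 0.3, n)
        cols["status"] = rng.integers(0, 2, n)
        ds = make_dataset(cols, targets=("status",))
        codes = ds.codes.copy()
        j = ds.index("lowcall")
        codes[: int(0.11 * n), j] = -1  # 89% call rate
        from bnbmla.data_model import DiscreteDataset
        ds = DiscreteDataset(ds.variables, codes)
        return ds

    def test_known_violations_partition(self):
        ds = self.build()
        controls = ds.column("status") == 0
        filtered, report = qc_filter(ds, controls)
        assert report.removed_monomorphic == ["mono"]
        assert report.removed_hwe == ["hwe_bad"]
        assert report.removed_callrate == ["lowcall"]
        assert len(report.retained) == 7
        total = (len(report.retained) + len(report.removed_monomorphic)
                 + len(report.removed_hwe) + len(report.removed_callrate))
        assert total == 10

    def test_clean_input_is_identity_and_idempotent(self):
        ds = self.build()
        controls = ds.column("status") == 0
        filtered, _ = qc_filter(ds, controls)
        again, report2 = qc_filter(filtered, controls)
        assert again.names == filtered.names
        assert not (report2.removed_monomorphic or report2.removed_hwe
                    or report2.removed_callrate)

    def test_hwe_violation_in_cases_only_is_retained(self):
        rng = np.random.default_rng(9)
        n = 400
        status = np.repeat([0, 1], n // 2)
        snp = np.concatenate([
            rng.binomial(1, 0.4, n // 2) + rng.binomial(1, 0.4, n // 2),
            np.where(rng.random(n // 2) < 0.5, 0, 2),  # cases out of HWE
        ])
        ds = make_dataset({"snp": snp, "status": status}, targets=("status",))
        _, report = qc_filter(ds, status == 0)
        assert report.retained == ["snp"]


class TestBonferroni:
    def test_corrected_level_for_many_markers(self):
        thr = bonferroni_threshold(0.05, 102)
        assert thr == pytest.approx(0.05 / 102)
        assert display_significance(thr) == pytest.approx(5e-4)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestHaplotypeOR:
    def test_protective_haplotype_from_printed_frequencies(self):
        res = haplotype_or_from_frequencies(0.528, 0.606, 872, 1530)
        assert round(res.odds_ratio, 2) == 0.73

    def test_risk_haplotype_from_reconstructed_counts(self):
        res = haplotype_or_from_frequencies(0.251, 0.191, 872, 1530)
        assert round(res.odds_ratio, 2) == 1.42

    def test_equal_frequencies_give_unit_odds(self):
        res = haplotype_or_from_frequencies(0.5, 0.5, 100, 100)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            haplotype_or_from_frequencies(0.0, 0.5, 100, 100)


class TestLogisticInteraction:
    def simulate(self, seed, n, beta_int):
        rng = np.random.default_rng(seed)
        g1 = rng.binomial(2, 0.4, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        eta = -0.5 + 0.3 * g1 + 0.2 * g2 + beta_int * g1 * g2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        terms = {"g1": g1, "g2": g2, "g1:g2": g1 * g2}
        return y, terms

    def test_null_interaction_ci_covers_unity(self):
        y, terms = self.simulate(seed=0, n=2000, beta_int=0.0)
        fit = {t.term: t for t in logistic_interaction_fit(y, terms)}
        inter = fit["g1:g2"]
        assert inter.ci_low <= 1.0 <= inter.ci_high

    def test_interaction_coefficient_recovery(self):
        y, terms = self.simulate(seed=1, n=5000, beta_int=0.5)
        fit = {t.term: t for t in logistic_interaction_fit(y, terms)}
        inter = fit["g1:g2"]
        se = (np.log(inter.ci_high) - np.log(inter.ci_low)) / (2 * 1.959964)
        assert abs(inter.coef - 0.5) < 2 * se

    def test_perfect_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1] * 3)
        terms = {"x": np.array([0, 0, 0, 1, 1, 1] * 3, dtype=float)}
        with pytest.raises(RuntimeError, match="x"):
            logistic_interaction_fit(y, terms)
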