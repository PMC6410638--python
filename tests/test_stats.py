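"""Association tests, prevalence machinery, co-mutation and cross-tabs."""

import math

import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from endopanel import (
    Cohort,
    ValidationError,
    comutation,
    crosstab,
    differential_screen,
    fisher_exact_two_sided,
    oncoprint_matrix,
    prevalence_table,
)
from endopanel import test_association as association_test
from endopanel import fixture_from_counts

from conftest import GROUP_SIZES, make_snv


def yates_oracle(a, b, c, d):
    """Closed-form continuity-corrected chi-square for a 2x2 table."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    stat = n * (abs(a * d - b * c) - n / 2) ** 2 / (r1 * r2 * c1 * c2)
    return stat, sps.chi2.sf(stat, 1)


class TestAssociation:
    def test_pten_table_uses_corrected_chi_square(self):
        res = association_test([[51, 28], [13, 23]])
        stat, p = yates_oracle(51, 28, 13, 23)
        assert res.test_used == "pearson_yates"
        assert res.statistic == pytest.approx(stat)
        assert res.p_two_sided == pytest.approx(p)
        assert res.p_two_sided == pytest.approx(0.008, abs=5e-4)

    def test_kdr_table_falls_back_to_fisher(self):
        res = association_test([[10, 69], [0, 36]])
        assert res.test_used == "fisher_exact"
        assert res.statistic is None
        assert res.p_two_sided == pytest.approx(0.030, abs=5e-4)
        # independent library cross-check
        assert res.p_two_sided == pytest.approx(
            sps.fisher_exact([[10, 69], [0, 36]])[1], abs=1e-9
        )

    def test_balanced_table_p_one(self):
        assert association_test([[5, 5], [5, 5]]).p_two_sided == pytest.approx(1.0)

    def test_zero_margin_falls_back_to_fisher(self):
        res = association_test([[0, 0], [3, 7]])
        assert res.test_used == "fisher_exact"
        assert res.p_two_sided == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            association_test([[1, -1], [0, 2]])

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_chi_square_symmetry(self, cells):
        """Swapping rows and/or columns never changes statistic or p."""
        a, b, c, d = cells
        base = association_test([[a, b], [c, d]])
        for t in ([[c, d], [a, b]], [[b, a], [d, c]], [[d, c], [b, a]]):
            other = association_test(t)
            assert other.test_used == base.test_used
            assert other.p_two_sided == pytest.approx(base.p_two_sided, abs=1e-12)
            if base.statistic is not None:
                assert other.statistic == pytest.approx(base.statistic, abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_fisher_matches_column_enumeration(self, cells):
        """Package Fisher equals an independent enumeration conditioned on
        the column margins (the implementation conditions on rows)."""
        a, b, c, d = cells
        p = fisher_exact_two_sided([[a, b], [c, d]])
        c1, c2 = a + c, b + d
        r1 = a + b
        n = a + b + c + d
        if n == 0:
            assert p == 1.0
            return
        lo, hi = max(0, r1 - c2), min(c1, r1)
        w_obs = math.comb(c1, a) * math.comb(c2, r1 - a)
        num = sum(
            math.comb(c1, x) * math.comb(c2, r1 - x)
            for x in range(lo, hi + 1)
            if math.comb(c1, x) * math.comb(c2, r1 - x) <= w_obs
        )
        assert p == pytest.approx(num / math.comb(n, r1), abs=1e-12)


class TestPrevalenceTable:
    def test_printed_percentages(self, prevalence_cohort):
        prev = prevalence_table(prevalence_cohort).set_index("gene")
        assert prev.loc["PIK3CA", "percentage"] == pytest.approx(46.1, abs=0.05)
        assert prev.loc["CTNNB1", "percentage"] == pytest.approx(29.6, abs=0.05)

    def test_min_mutated_threshold(self):
        cohort = fixture_from_counts((20, 10), {"A": (6, 2), "B": (9, 0)},
                                     panel={"A": 1000, "B": 1000})
        prev = prevalence_table(cohort, min_mutated=9)
        assert list(prev["gene"]) == ["B"]

    def test_sorted_by_count_then_name(self, prevalence_cohort):
        prev = prevalence_table(prevalence_cohort)
        counts = list(prev["mutated_overall"])
        assert counts == sorted(counts, reverse=True)
        assert list(prev["gene"])[:2] == ["PTEN", "PIK3CA"]

    def test_marginal_conservation(self, prevalence_cohort):
        prev = prevalence_table(prevalence_cohort)
        assert (prev["mutated_eec"] + prev["mutated_ein"] == prev["mutated_overall"]).all()

    def test_sample_counted_once_per_gene(self):
        cohort = fixture_from_counts((2, 0), {"A": (1, 0)}, panel={"A": 1000})
        cohort.somatic.append(make_snv(sample_id="EEC_001", gene="A", pos=555))
        prev = prevalence_table(cohort).set_index("gene")
        assert prev.loc["A", "mutated_overall"] == 1


class TestComutation:
    @pytest.fixture()
    def comut_cohort(self):
        cohort = fixture_from_counts(GROUP_SIZES, {})
        # 24 EEC and 4 EIN samples carry both PTEN and PIK3CA
        for i in range(24):
            cohort.somatic += [
                make_snv(sample_id=f"EEC_{i+1:03d}", gene="PTEN"),
                make_snv(sample_id=f"EEC_{i+1:03d}", gene="PIK3CA"),
            ]
        for i in range(4):
            cohort.somatic += [
                make_snv(sample_id=f"EIN_{i+1:03d}", gene="PTEN"),
                make_snv(sample_id=f"EIN_{i+1:03d}", gene="PIK3CA"),
            ]
        # extra single-gene carriers must not count as co-mutated
        cohort.somatic.append(make_snv(sample_id="EEC_050", gene="PTEN"))
        return cohort

    def test_printed_shares_and_p(self, comut_cohort):
        res = comutation(comut_cohort, "PTEN", "PIK3CA")
        assert (res.n_co_eec, res.n_co_ein) == (24, 4)
        assert res.share_eec == pytest.approx(0.304, abs=5e-4)
        assert res.share_ein == pytest.approx(0.111, abs=5e-4)
        assert res.association.p_two_sided == pytest.approx(0.046, abs=5e-4)

    def test_same_gene_reduces_to_single_gene_set(self, comut_cohort):
        res = comutation(comut_cohort, "PTEN", "PTEN")
        assert res.n_co_eec == 25  # 24 co-mutated + 1 PTEN-only carrier

    def test_no_carriers_zero_safe(self):
        cohort = fixture_from_counts((3, 3), {}, panel={"A": 1000, "B": 1000})
        res = comutation(cohort, "A", "B")
        assert res.share_eec == res.share_ein == 0.0


class TestDifferentialScreen:
    def test_significant_set_matches_count_table(self, prevalence_cohort):
        screen = differential_screen(prevalence_cohort, alpha=0.05)
        assert set(screen.significant) == {
            "PTEN", "PIK3R1", "ARID1A", "CTCF", "ARHGAP35", "KDR", "AKT1",
        }
        p = screen.results.set_index("gene")["p_two_sided"]
        assert p["NF1"] == pytest.approx(0.055, abs=5e-4)
        assert p["TP53"] == pytest.approx(0.055, abs=5e-4)

    def test_alpha_zero_empty(self, prevalence_cohort):
        assert differential_screen(prevalence_cohort, alpha=0.0).significant == []

    def test_single_gene(self):
        cohort = fixture_from_counts((10, 10), {"A": (8, 1)}, panel={"A": 1000})
        screen = differential_screen(cohort)
        assert len(screen.results) == 1

    def test_bh_correction_is_weaker_or_equal(self, prevalence_cohort):
        raw = differential_screen(prevalence_cohort, correction="none")
        bh = differential_screen(prevalence_cohort, correction="BH")
        assert set(bh.significant) <= set(raw.significant)
        assert (bh.results["p_adjusted"] >= bh.results["p_two_sided"] - 1e-15).all()

    def test_deterministic_report(self, prevalence_cohort):
        a = differential_screen(prevalence_cohort).results.to_csv()
        b = differential_screen(prevalence_cohort).results.to_csv()
        assert a == b


class TestCrosstab:
    @pytest.fixture()
    def graded_cohort(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "group": ["EEC", "EEC", "EEC", "EIN"],
                "grade": ["G1", "G2", "G3", "."],
                "stage": ["IA", "IA", "II", "."],
            }
        )
        somatic = [make_snv(sample_id="S1", gene="CTNNB1"),
                   make_snv(sample_id="S2", gene="CTNNB1")]
        return Cohort(samples=samples, somatic=somatic)

    def test_empty_level_retained(self, graded_cohort):
        tab = crosstab(graded_cohort, "CTNNB1", "grade").set_index("level")
        assert tab.loc["G3", "mutated_samples"] == 0
        assert tab.loc["G1", "mutated_samples"] == 1

    def test_totals_conserved(self, graded_cohort):
        tab = crosstab(graded_cohort, "CTNNB1", "grade")
        assert tab["mutated_samples"].sum() == 2

    def test_unknown_covariate_rejected(self, graded_cohort):
        with pytest.raises(ValidationError):
            crosstab(graded_cohort, "CTNNB1", "age")


def test_oncoprint_matrix_class_codes(prevalence_cohort):
    mat = oncoprint_matrix(prevalence_cohort)
    assert mat.loc["PTEN", "EEC_001"] == "M"  # fixture variants are missense
    assert (mat.loc["KDR", [f"EIN_{i+1:03d}" for i in range(36)]] == ".").all()
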