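"""Depth-ratio CNV caller: LRR, region classes, majority rule, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endopanel import (
    CnvThresholds,
    CohortConfig,
    RegionDepthPair,
    ValidationError,
    call_cohort,
    call_gene_cnv,
    classify_region,
    cna_summary,
    cnv_matrix,
    generate_cohort,
    region_lrr,
)
from endopanel.cnv import NOT_EVALUABLE, call_from_classifications


def pair(tumor, normal, gene="G", idx=0):
    return RegionDepthPair(
        gene=gene, region_index=idx, chrom="chr1", start=idx * 100,
        end=idx * 100 + 100, tumor_depth=tumor, normal_depth=normal,
    )


class TestRegionLrr:
    @pytest.mark.parametrize(
        "tumor,normal,expected",
        [(200, 100, 1.0), (100, 100, 0.0), (50, 100, -1.0)],
    )
    def test_log2_ratio(self, tumor, normal, expected):
        assert region_lrr(pair(tumor, normal)) == pytest.approx(expected)

    @pytest.mark.parametrize("tumor,normal", [(100, 0), (0, 100), (100, 19.9)])
    def test_degenerate_depths_not_evaluable(self, tumor, normal):
        assert math.isnan(region_lrr(pair(tumor, normal)))

    def test_no_infinities_ever(self):
        assert not math.isinf(region_lrr(pair(1e9, 0)))


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "lrr,expected",
        [
            (0.40, "amp"),
            (0.35, "neutral"),  # strict inequality at the amplification bound
            (-0.60, "del"),
            (-0.50, "neutral"),  # strict at the deletion bound
            (0.0, "neutral"),
            (math.nan, NOT_EVALUABLE),
        ],
    )
    def test_thresholds_strict(self, lrr, expected):
        assert classify_region(lrr) == expected


class TestCallGene:
    def test_eight_of_ten_amplified(self):
        classes = ["amp"] * 8 + ["neutral"] * 2
        call = call_from_classifications("G", "S", classes)
        assert call.call == "amplification"
        assert call.supporting_fraction == pytest.approx(0.8)

    def test_seven_of_ten_is_no_call(self):
        call = call_from_classifications("G", "S", ["amp"] * 7 + ["neutral"] * 3)
        assert call.call == "none"  # 0.7 is not > 0.7

    def test_all_deleted(self):
        call = call_from_classifications("G", "S", ["del"] * 10)
        assert call.call == "deletion"

    def test_not_evaluable_excluded_from_denominator(self):
        classes = ["amp"] * 8 + [NOT_EVALUABLE] * 4 + ["neutral"] * 2
        call = call_from_classifications("G", "S", classes)
        assert call.n_regions == 10 and call.n_total == 14
        assert call.call == "amplification"

    def test_zero_evaluable_is_reasoned_no_call(self):
        call = call_from_classifications("G", "S", [NOT_EVALUABLE] * 3)
        assert call.call == "none" and call.reason == "no evaluable regions"
        assert call.supporting_fraction is None

    def test_from_depth_pairs(self):
        regions = [pair(300, 100, idx=i) for i in range(8)] + [
            pair(100, 100, idx=i) for i in range(8, 10)
        ]
        assert call_gene_cnv(regions, sample_id="S").call == "amplification"

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(1, 30), st.floats(0.05, 0.95))
    def test_exact_majority_threshold_never_calls(self, n, majority):
        """A fraction exactly at the majority threshold yields no call."""
        k = round(majority * n)
        if k == 0 or abs(k / n - majority) > 1e-12:
            return  # threshold not exactly attainable for this n
        thresholds = CnvThresholds(majority=majority)
        call = call_from_classifications("G", "S", ["amp"] * k + ["neutral"] * (n - k), thresholds)
        assert call.call == "none"

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            CnvThresholds(amp_lrr=-0.1)
        with pytest.raises(ValidationError):
            CnvThresholds(majority=1.0)


def _profile_frame(samples, genes, n_regions, tumor, normal):
    rows = []
    for s in samples:
        for g in genes:
            for i in range(n_regions):
                rows.append(
                    {
                        "sample_id": s, "chrom": "chr1", "start": i * 100,
                        "end": i * 100 + 100, "gene": g, "region_index": i,
                        "tumor_depth": tumor, "normal_depth": normal,
                    }
                )
    return pd.DataFrame(rows)


class TestCohortLevel:
    def test_null_profile_yields_zero_calls(self):
        df = _profile_frame(["S1", "S2"], ["A", "B"], 10, 500.0, 500.0)
        calls = call_cohort(df)
        assert all(c.call == "none" for c in calls)

    def test_tumor_scaling_shifts_lrr_exactly(self):
        rng = np.random.default_rng(0)
        depths = rng.integers(100, 3000, size=50).astype(float)
        base = [pair(t, n, idx=i) for i, (t, n) in enumerate(zip(depths, depths[::-1]))]
        for c in (1.0, 0.37, -2.0):
            shifted = [
                pair(r.tumor_depth * 2.0 ** c, r.normal_depth, idx=r.region_index)
                for r in base
            ]
            lrr0 = np.array([region_lrr(r) for r in base])
            lrr1 = np.array([region_lrr(r) for r in shifted])
            np.testing.assert_allclose(lrr1, lrr0 + c, atol=1e-12)

    def test_spiked_gene_recovered_in_carriers(self):
        """Seeded synthetic cohort: a +1 log2 spike across all regions is
        called amplified in >= 95% of true carriers."""
        cohort = generate_cohort(CohortConfig(seed=20, region_genes=["VEGFB"]))
        true_carriers = set(cohort.truth["cnv_carriers"]["VEGFB"])
        calls = call_cohort(cohort.region_depths)
        amp = {c.sample_id for c in calls if c.gene == "VEGFB" and c.call == "amplification"}
        assert len(true_carriers) > 0
        assert len(amp & true_carriers) / len(true_carriers) >= 0.95

    def test_cna_summary_printed_ratios(self):
        # 48 of 115 samples carry >= 1 CNA; VEGFB amplified in 19 EEC + 1 EIN
        samples = pd.DataFrame(
            {
                "sample_id": [f"EEC_{i}" for i in range(79)] + [f"EIN_{i}" for i in range(36)],
                "group": ["EEC"] * 79 + ["EIN"] * 36,
                "grade": ".", "stage": ".",
            }
        )
        calls = []
        carriers = [f"EEC_{i}" for i in range(19)] + ["EIN_0"]
        for s in carriers:
            calls.append(_call(s, "VEGFB", "amplification"))
        extra = [f"EEC_{i}" for i in range(19, 47)]  # 28 more affected samples
        for s in extra:
            calls.append(_call(s, "OTHER", "deletion"))
        summary = cna_summary(calls, samples)
        assert summary.n_affected == 48
        assert summary.affected_fraction == pytest.approx(48 / 115)  # 41.7%
        vegfb = summary.per_gene.set_index("gene").loc["VEGFB"]
        assert vegfb.n_carriers == 20
        assert vegfb.share_EEC == pytest.approx(0.95)

    def test_empty_summary(self):
        samples = pd.DataFrame(
            {"sample_id": ["S1"], "group": ["EEC"], "grade": ["."], "stage": ["."]}
        )
        summary = cna_summary([], samples)
        assert summary.n_affected == 0 and summary.median_cnas_per_sample == 0

    def test_cnv_matrix_codes(self):
        calls = [_call("S1", "G1", "amplification"), _call("S2", "G2", "deletion")]
        mat = cnv_matrix(calls, ["S1", "S2"])
        assert mat.loc["G1", "S1"] == "A"
        assert mat.loc["G2", "S2"] == "D"
        assert mat.loc["G1", "S2"] == "."


def _call(sample_id, gene, call):
    from endopanel import GeneCnvCall

    return GeneCnvCall(
        gene=gene, sample_id=sample_id, call=call, n_regions=10,
        n_amp=10 if call == "amplification" else 0,
        n_del=10 if call == "deletion" else 0,
        supporting_fraction=1.0, n_total=10,
    )
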