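"""Variant model: QC filter semantics, exon/recurrence/class summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endopanel import (
    FilterPolicy,
    ValidationError,
    VariantCall,
    exon_fraction,
    filter_qualifying_snvs,
    recurrent_variants,
    variant_class_breakdown,
)
from endopanel.variants import normalize_variant_class

from conftest import make_snv


class TestFilterQualifyingSnvs:
    @pytest.mark.parametrize(
        "depth,vaf,expected",
        [
            (150, 0.10, False),  # depth bound is strict: 150 fails >150
            (151, 0.03, True),  # VAF bound is inclusive: 0.03 passes
            (151, 0.0299, False),
            (10_000, 1.0, True),
        ],
    )
    def test_depth_and_vaf_bounds(self, depth, vaf, expected):
        v = make_snv(depth=depth, vaf=vaf)
        assert (v in filter_qualifying_snvs([v])) is expected

    def test_indels_excluded_by_default_but_includable(self):
        indel = VariantCall(
            sample_id="S1", gene="PTEN", chrom="chr1", pos=5, ref="CAT", alt="C",
            variant_type="deletion", variant_class="frameshift", depth=500, vaf=0.3,
        )
        assert filter_qualifying_snvs([indel]) == []
        relaxed = FilterPolicy(snv_only_for_tmb=False)
        assert filter_qualifying_snvs([indel], relaxed) == [indel]

    def test_empty_input(self):
        assert filter_qualifying_snvs([]) == []

    def test_order_preserved(self):
        vs = [make_snv(sample_id=f"S{i}", depth=200 + i) for i in range(5)]
        assert filter_qualifying_snvs(vs) == vs


_variant_strategy = st.builds(
    make_snv,
    sample_id=st.sampled_from(["S1", "S2"]),
    depth=st.integers(min_value=0, max_value=400),
    vaf=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
)


@settings(max_examples=100, derandomize=True)
@given(st.lists(_variant_strategy, max_size=30), st.integers(0, 30))
def test_filter_idempotent_and_partitionable(variants, split):
    """Filtering twice equals once; filtering parts and concatenating equals
    filtering the whole."""
    once = filter_qualifying_snvs(variants)
    assert filter_qualifying_snvs(once) == once
    k = min(split, len(variants))
    parts = filter_qualifying_snvs(variants[:k]) + filter_qualifying_snvs(variants[k:])
    assert parts == once


class TestExonFraction:
    @pytest.mark.parametrize(
        "gene,n_in,n_out,exon,expected",
        [
            ("CTNNB1", 31, 8, 3, 0.795),  # 31/39 in exon 3
            ("ARID1A", 21, 28, 20, 0.429),  # 21/49 in exon 20
        ],
    )
    def test_printed_exon_shares(self, gene, n_in, n_out, exon, expected):
        vs = [make_snv(gene=gene, exon=exon) for _ in range(n_in)]
        vs += [make_snv(gene=gene, exon=exon + 1) for _ in range(n_out)]
        res = exon_fraction(vs, gene, exon)
        assert (res.count_in_exon, res.total) == (n_in, n_in + n_out)
        assert res.fraction == pytest.approx(expected, abs=5e-4)

    def test_unknown_exon_counts_toward_total_only(self):
        vs = [make_snv(exon=3), make_snv(exon=None)]
        res = exon_fraction(vs, "PTEN", 3)
        assert (res.count_in_exon, res.total, res.fraction) == (1, 2, 0.5)

    def test_no_variants_gives_undefined_fraction(self):
        res = exon_fraction([], "PTEN", 3)
        assert res.total == 0 and res.fraction is None


class TestRecurrentVariants:
    def test_kras_hotspot_ranking(self):
        # 7x G12V, 5x G12D, 2x Q61H plus 4 unannotated = 18 gene variants
        vs = (
            [make_snv(gene="KRAS", protein_change="p.G12V") for _ in range(7)]
            + [make_snv(gene="KRAS", protein_change="p.G12D") for _ in range(5)]
            + [make_snv(gene="KRAS", protein_change="p.Q61H") for _ in range(2)]
            + [make_snv(gene="KRAS") for _ in range(4)]
        )
        ranked = recurrent_variants(vs, "KRAS")
        assert [r[0] for r in ranked] == ["p.G12V", "p.G12D", "p.Q61H"]
        assert ranked[0][2] == pytest.approx(7 / 18)  # 38.9%
        assert ranked[1][2] == pytest.approx(5 / 18)  # 27.8%
        assert ranked[2][2] == pytest.approx(2 / 18)  # 11.1%

    def test_single_variant_full_share(self):
        ranked = recurrent_variants([make_snv(protein_change="p.T41I")], "PTEN")
        assert ranked == [("p.T41I", 1, 1.0)]

    def test_tie_broken_lexicographically(self):
        vs = [make_snv(protein_change="p.B2C"), make_snv(protein_change="p.A1B")]
        ranked = recurrent_variants(vs, "PTEN")
        assert [r[0] for r in ranked] == ["p.A1B", "p.B2C"]


class TestVariantClassBreakdown:
    def test_printed_class_shares(self):
        vs = (
            [make_snv(gene="CTCF", variant_class="frameshift") for _ in range(5)]
            + [make_snv(gene="CTCF", variant_class="nonsense") for _ in range(7)]
            + [make_snv(gene="CTCF", variant_class="other") for _ in range(3)]
        )
        shares = variant_class_breakdown(vs, "CTCF")
        assert shares["frameshift"] == pytest.approx(1 / 3)  # 33.3%
        assert shares["nonsense"] == pytest.approx(7 / 15)  # 46.7%
        assert shares["other"] == pytest.approx(0.2)

    def test_all_missense(self):
        assert variant_class_breakdown([make_snv()], "PTEN") == {"missense": 1.0}

    def test_empty(self):
        assert variant_class_breakdown([], "PTEN") == {}

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["missense", "nonsense", "frameshift", "other"]),
                    min_size=1, max_size=40))
    def test_shares_sum_to_one(self, classes):
        vs = [make_snv(variant_class=c) for c in classes]
        assert sum(variant_class_breakdown(vs, "PTEN").values()) == pytest.approx(1.0, abs=1e-12)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(depth=-1), "depth"),
            (dict(vaf=1.5), "vaf"),
            (dict(variant_type="MNV"), "variant_type"),
            (dict(variant_class="weird"), "variant_class"),
            (dict(zygosity="homo"), "zygosity"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, field):
        base = dict(
            sample_id="S1", gene="PTEN", chrom="chr1", pos=1, ref="C", alt="T",
            variant_type="SNV", variant_class="missense", depth=10, vaf=0.1,
        )
        base.update(kwargs)
        with pytest.raises(ValidationError, match=field):
            VariantCall(**base)

    def test_type_allele_consistency(self):
        with pytest.raises(ValidationError, match="variant_type"):
            VariantCall(
                sample_id="S1", gene="G", chrom="chr1", pos=1, ref="CAT", alt="T",
                variant_type="SNV", variant_class="missense", depth=1, vaf=0.1,
            )

    def test_class_normalization(self):
        assert normalize_variant_class("Missense_Mutation") == "missense"
        assert normalize_variant_class("stopgain") == "nonsense"
        assert normalize_variant_class("completely-novel") == "other"
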