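import pytest

from endopanel import Cohort, VariantCall, fixture_from_counts

#: Recurrently mutated genes: gene -> (mutated_eec, mutated_ein) out of 79/36.
TABLE2_COUNTS = {
    "PTEN": (51, 13), "PIK3CA": (37, 16), "CTNNB1": (22, 12), "PIK3R1": (30, 4),
    "ARID1A": (29, 4), "KRAS": (12, 6), "CTCF": (15, 0), "FGFR2": (12, 2),
    "ARID5B": (11, 2), "NOTCH1": (9, 3), "ARHGAP35": (12, 0), "KMT2D": (10, 2),
    "MTOR": (10, 1), "SMC1A": (9, 1), "BRCA2": (9, 1), "KDR": (10, 0),
    "AKT1": (3, 6), "APC": (8, 1), "KMT2B": (7, 2), "ERBB3": (7, 2),
    "NF1": (9, 0), "TP53": (9, 0), "POLQ": (8, 1),
}

GROUP_SIZES = (79, 36)  # (n_eec, n_ein)


def make_snv(
    sample_id="S1",
    gene="PTEN",
    depth=500,
    vaf=0.30,
    variant_class="missense",
    exon=None,
    protein_change=None,
    origin="somatic",
    zygosity=None,
    pathogenicity=None,
    pos=101,
):
    return VariantCall(
        sample_id=sample_id, gene=gene, chrom="chr1", pos=pos, ref="C", alt="T",
        variant_type="SNV", variant_class=variant_class, depth=depth, vaf=vaf,
        exon=exon, protein_change=protein_change, origin=origin,
        zygosity=zygosity, pathogenicity=pathogenicity,
    )


@pytest.fixture(scope="session")
def prevalence_cohort() -> Cohort:
    """Deterministic cohort reproducing the recurrent-gene count table."""
    return fixture_from_counts(GROUP_SIZES, TABLE2_COUNTS)
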