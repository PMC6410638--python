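"""Synthetic sequencing-cohort generator.

Emulates the statistical structure of a two-group targeted-panel study of
endometrioid endometrial carcinoma (EEC) and its precursor lesion (EIN):
per-gene group-specific mutation prevalence, a small hypermutator
subpopulation driven by DNA-damage-repair (DDR) gene mutations, negative-
binomial sequencing-depth noise, Beta-distributed variant allele fractions,
paired tumor/normal per-region depth profiles with configurable copy-number
spike-ins, and directly-assigned germline pathogenicity labels.

Defaults reproduce the cohort conditions of the study design this package
models: 36 EIN + 79 EEC samples, per-gene prevalences taken from the
observed group frequencies of the recurrently mutated panel genes, mean
on-target depths of 1690x (tumor) and 2389x (normal), a ~4% hypermutator
fraction, and a VEGFB amplification carried predominantly by carcinomas.

The panel shipped here is a synthetic ~40-gene toy panel (gene list plus
plausible coding-footprint sizes); the real 363-gene design is proprietary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import GROUP_EEC, GROUP_EIN, Cohort
from .errors import ConfigurationError, ValidationError
from .tmb import DEFAULT_DDR_GENES
from .variants import GERMLINE, SOMATIC, VariantCall

# -- default study conditions --------------------------------------------------

#: gene -> (prob_ein, prob_eec): observed group mutation frequencies of the
#: recurrently mutated genes (carriers / group size).
DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "PTEN": (13 / 36, 51 / 79),
    "PIK3CA": (16 / 36, 37 / 79),
    "CTNNB1": (12 / 36, 22 / 79),
    "PIK3R1": (4 / 36, 30 / 79),
    "ARID1A": (4 / 36, 29 / 79),
    "KRAS": (6 / 36, 12 / 79),
    "CTCF": (0 / 36, 15 / 79),
    "FGFR2": (2 / 36, 12 / 79),
    "ARID5B": (2 / 36, 11 / 79),
    "NOTCH1": (3 / 36, 9 / 79),
    "ARHGAP35": (0 / 36, 12 / 79),
    "KMT2D": (2 / 36, 10 / 79),
    "MTOR": (1 / 36, 10 / 79),
    "SMC1A": (1 / 36, 9 / 79),
    "BRCA2": (1 / 36, 9 / 79),
    "KDR": (0 / 36, 10 / 79),
    "AKT1": (6 / 36, 3 / 79),
    "APC": (1 / 36, 8 / 79),
    "KMT2B": (2 / 36, 7 / 79),
    "ERBB3": (2 / 36, 7 / 79),
    "NF1": (0 / 36, 9 / 79),
    "TP53": (0 / 36, 9 / 79),
    "POLQ": (1 / 36, 8 / 79),
}

#: Synthetic toy panel: gene -> targeted footprint in bp (roughly the coding
#: size of each gene; stand-in for the real, unpublished panel design).
DEFAULT_PANEL: dict[str, int] = {
    "PTEN": 1300, "PIK3CA": 3300, "CTNNB1": 2400, "PIK3R1": 2200,
    "ARID1A": 6900, "KRAS": 600, "CTCF": 2200, "FGFR2": 2500,
    "ARID5B": 3600, "NOTCH1": 7700, "ARHGAP35": 4600, "KMT2D": 16600,
    "MTOR": 7700, "SMC1A": 3700, "BRCA2": 10300, "KDR": 4100,
    "AKT1": 1500, "APC": 8500, "KMT2B": 8200, "ERBB3": 4100,
    "NF1": 8500, "TP53": 1200, "POLQ": 7700, "POLE": 6900,
    "MSH2": 2800, "MSH6": 4100, "MLH1": 2300, "MLH3": 4400,
    "PMS1": 2800, "PMS2": 2600, "MUTYH": 1600, "GALNT12": 1800,
    "MPL": 1900, "ATM": 9200, "ERCC4": 2800, "VEGFB": 600,
}


@dataclass(frozen=True)
class CnvSpike:
    """A true copy-number event planted in the region-depth profiles."""

    gene: str
    group: str  # EEC or EIN
    carrier_fraction: float  # fraction of the group's samples carrying it
    log2_fold: float  # true tumor-depth fold change, log2 scale


#: VEGFB amplification carried by 19/79 carcinomas and 1/36 precursors.
DEFAULT_CNV_SPIKES: tuple[CnvSpike, ...] = (
    CnvSpike("VEGFB", GROUP_EEC, 19 / 79, 1.0),
    CnvSpike("VEGFB", GROUP_EIN, 1 / 36, 1.0),
)

#: Pathogenic/likely-pathogenic germline finding templates (gene, HGVS-like
#: change, zygosity, label, variant class/type) used by the simulator.
DEFAULT_GERMLINE_TEMPLATES: tuple[tuple[str, str, str, str, str, str], ...] = (
    ("MUTYH", "c.934-2A>G", "hom", "pathogenic", "splice", "SNV"),
    ("MLH1", "c.885-1_893delGTTTAGAAAT", "hom", "pathogenic", "frameshift", "deletion"),
    ("MSH2", "c.C1183T (p.Q395X)", "hom", "pathogenic", "nonsense", "SNV"),
    ("GALNT12", "c.G5A (p.W2X)", "hom", "likely_pathogenic", "nonsense", "SNV"),
    ("POLE", "c.4430delG (p.S1477Tfs)", "het", "likely_pathogenic", "frameshift", "deletion"),
    ("MPL", "c.313_316delTTTC (p.F105Rfs)", "het", "likely_pathogenic", "frameshift", "deletion"),
    ("ATM", "c.C8494T (p.R2832C)", "het", "likely_pathogenic", "missense", "SNV"),
    ("MUTYH", "c.G467A (p.W156X)", "het", "pathogenic", "nonsense", "SNV"),
    ("ERCC4", "c.1536dupA (p.G513Rfs)", "het", "likely_pathogenic", "frameshift", "insertion"),
    ("MPL", "c.981-1G>C", "het", "pathogenic", "splice", "SNV"),
)

_EEC_GRADE_PROBS = {"G1": 40 / 79, "G2": 24 / 79, "G3": 15 / 79}
_EEC_STAGE_PROBS = {
    "IA": 61 / 79, "IB": 4 / 79, "II": 3 / 79, "IIIA": 4 / 79,
    "IIIB": 2 / 79, "IIIC": 4 / 79, "IV": 1 / 79,
}

_BASES = np.array(list("ACGT"))
_AA = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the modeled study design.

    ``prevalence`` maps gene -> (prob_ein, prob_eec); these genes' carrier
    status is drawn exactly Bernoulli, so observed frequencies converge to
    the configured values. Background mutations (negative binomial counts
    around ``background_mean`` for non-hypermutators, around
    ``hypermutator_mean`` for hypermutators; defaults give per-tumor counts
    of roughly 0-48 and 140-280 respectively) are scattered over the panel
    genes *outside* the prevalence map so they cannot distort it.

    Per-variant read depths are negative binomial around the configured
    means with ``depth_dispersion`` as the NB size parameter; VAFs are Beta
    with the given mean and concentration. Region-depth profiles model
    mean depth over ~100 bp windows, hence the much tighter
    ``region_depth_dispersion``; copy-neutral regions are generated with
    equal tumor and normal expectation (expected LRR 0), emulating
    library-size-normalized coverage as a depth-ratio caller assumes.
    ``region_genes=None`` profiles every panel gene; an empty list skips
    depth-profile generation entirely.
    """

    n_ein: int = 36
    n_eec: int = 79
    prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    hypermutator_fraction: float = 5 / 115
    background_mean: float = 7.0
    hypermutator_mean: float = 185.0
    count_dispersion: float = 2.0
    hypermutator_count_dispersion: float = 30.0
    mean_tumor_depth: float = 1690.0
    mean_normal_depth: float = 2389.0
    depth_dispersion: float = 8.0
    region_depth_dispersion: float = 150.0
    vaf_mean: float = 0.25
    vaf_concentration: float = 8.0
    indel_fraction: float = 0.10
    cnv_spikes: tuple[CnvSpike, ...] = DEFAULT_CNV_SPIKES
    germline_pathogenic_rate_eec: float = 10 / 79
    germline_pathogenic_rate_ein: float = 0.0
    germline_noise_rate: float = 0.05
    panel: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL))
    region_bp: int = 100
    region_genes: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ein < 0 or self.n_eec < 0:
            raise ConfigurationError("group sizes must be >= 0")
        for gene, (p_ein, p_eec) in self.prevalence.items():
            if not (0 <= p_ein <= 1 and 0 <= p_eec <= 1):
                raise ConfigurationError(
                    f"prevalence for {gene} must be probabilities in [0, 1], "
                    f"got ({p_ein}, {p_eec})"
                )
        for name in ("hypermutator_fraction", "indel_fraction", "vaf_mean",
                     "germline_pathogenic_rate_eec", "germline_pathogenic_rate_ein",
                     "germline_noise_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mean_tumor_depth <= 0 or self.mean_normal_depth <= 0:
            raise ConfigurationError("mean depths must be > 0")
        for sp in self.cnv_spikes:
            if sp.gene not in self.panel:
                raise ConfigurationError(f"cnv spike gene {sp.gene!r} not in panel")
            if not (0 <= sp.carrier_fraction <= 1):
                raise ConfigurationError("cnv spike carrier_fraction must be in [0, 1]")
            if sp.group not in (GROUP_EEC, GROUP_EIN):
                raise ConfigurationError(f"cnv spike group must be EEC/EIN, got {sp.group!r}")

    @property
    def panel_mb(self) -> float:
        return sum(self.panel.values()) / 1e6


def gene_locus(gene: str, panel: dict[str, int]) -> tuple[str, int, int]:
    """Deterministic synthetic coordinates for a panel gene (chrom, start, end)."""
    genes = sorted(panel)
    if gene not in panel:
        raise ValidationError(f"gene {gene!r} not in panel")
    i = genes.index(gene)
    start = 1_000_000 * (i + 1)
    return f"chr{(i % 22) + 1}", start, start + panel[gene]


def _nb(rng: np.random.Generator, mean: float, k: float, size) -> np.ndarray:
    """Negative binomial with given mean and size (dispersion) parameter k."""
    return rng.negative_binomial(k, k / (k + mean), size=size)


def _beta_vaf(rng: np.random.Generator, mean: float, conc: float, size) -> np.ndarray:
    a = max(mean * conc, 1e-6)
    b = max((1 - mean) * conc, 1e-6)
    return np.clip(rng.beta(a, b, size=size), 1e-6, 1.0)


def _make_samples(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_ein):
        rows.append({"sample_id": f"EIN_{i + 1:03d}", "group": GROUP_EIN,
                     "grade": ".", "stage": "."})
    grades = rng.choice(list(_EEC_GRADE_PROBS), size=config.n_eec,
                        p=list(_EEC_GRADE_PROBS.values()))
    stages = rng.choice(list(_EEC_STAGE_PROBS), size=config.n_eec,
                        p=list(_EEC_STAGE_PROBS.values()))
    for i in range(config.n_eec):
        rows.append({"sample_id": f"EEC_{i + 1:03d}", "group": GROUP_EEC,
                     "grade": grades[i], "stage": stages[i]})
    return pd.DataFrame(rows, columns=["sample_id", "group", "grade", "stage"])


def _somatic_variant(
    rng: np.random.Generator,
    config: CohortConfig,
    sample_id: str,
    gene: str,
) -> VariantCall:
    chrom, gstart, gend = gene_locus(gene, config.panel)
    pos = int(rng.integers(gstart + 1, gend + 1))  # 1-based point position
    is_indel = rng.random() < config.indel_fraction
    if is_indel:
        if rng.random() < 0.5:
            vtype = "deletion"
            ref = "".join(rng.choice(_BASES, size=int(rng.integers(2, 8))))
            alt = ref[0]
        else:
            vtype = "insertion"
            alt = "".join(rng.choice(_BASES, size=int(rng.integers(2, 8))))
            ref = alt[0]
        vclass = "frameshift" if rng.random() < 0.8 else "nonframeshift_indel"
    else:
        vtype = "SNV"
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        vclass = rng.choice(
            ["missense", "nonsense", "splice", "synonymous"], p=[0.62, 0.12, 0.06, 0.20]
        )
    n_exons = max(2, config.panel[gene] // 150)
    aa_pos = max(1, (pos - gstart) // 3)
    protein = None
    if vclass in {"missense", "nonsense"}:
        a1, a2 = rng.choice(_AA, size=2)
        protein = f"p.{a1}{aa_pos}{'X' if vclass == 'nonsense' else a2}"
    elif vclass == "frameshift":
        protein = f"p.{rng.choice(_AA)}{aa_pos}fs"
    return VariantCall(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos,
        ref=str(ref), alt=str(alt), variant_type=str(vtype), variant_class=str(vclass),
        depth=int(_nb(rng, config.mean_tumor_depth, config.depth_dispersion, None)),
        vaf=float(_beta_vaf(rng, config.vaf_mean, config.vaf_concentration, None)),
        exon=int(rng.integers(1, n_exons + 1)),
        protein_change=protein, origin=SOMATIC,
    )


def _region_depths(
    config: CohortConfig,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    genes = (
        sorted(config.panel)
        if config.region_genes is None
        else list(config.region_genes)
    )
    for g in genes:
        if g not in config.panel:
            raise ConfigurationError(f"region gene {g!r} not in panel")
    sample_ids = samples["sample_id"].to_numpy()
    group_of = samples.set_index("sample_id")["group"]
    carriers_by_gene: dict[str, set[str]] = {}
    frames = []
    for gene in genes:
        chrom, gstart, gend = gene_locus(gene, config.panel)
        n_regions = max(1, config.panel[gene] // config.region_bp)
        starts = gstart + config.region_bp * np.arange(n_regions)
        ends = np.minimum(starts + config.region_bp, gend)
        # copy-neutral baseline: equal tumor/normal expectation (LRR 0)
        baseline = config.mean_normal_depth
        tumor = _nb(rng, baseline, config.region_depth_dispersion,
                    (len(sample_ids), n_regions)).astype(float)
        normal = _nb(rng, baseline, config.region_depth_dispersion,
                     (len(sample_ids), n_regions)).astype(float)
        for sp in config.cnv_spikes:
            if sp.gene != gene:
                continue
            members = [s for s in sample_ids if group_of[s] == sp.group]
            n_carry = int(round(sp.carrier_fraction * len(members)))
            chosen = rng.choice(members, size=n_carry, replace=False) if n_carry else []
            idx = [list(sample_ids).index(s) for s in chosen]
            tumor[idx, :] *= 2.0 ** sp.log2_fold
            carriers_by_gene.setdefault(gene, set()).update(chosen)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_ids, n_regions),
                    "chrom": chrom,
                    "start": np.tile(starts, len(sample_ids)),
                    "end": np.tile(ends, len(sample_ids)),
                    "gene": gene,
                    "region_index": np.tile(np.arange(n_regions), len(sample_ids)),
                    "tumor_depth": tumor.ravel(),
                    "normal_depth": normal.ravel(),
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "gene",
                     "region_index", "tumor_depth", "normal_depth"]
        )
    )
    return df, {g: sorted(s) for g, s in carriers_by_gene.items()}


def _germline(
    config: CohortConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> list[VariantCall]:
    out = []
    template_i = 0
    panel_genes = sorted(config.panel)
    for _, row in samples.iterrows():
        rate = (
            config.germline_pathogenic_rate_eec
            if row.group == GROUP_EEC
            else config.germline_pathogenic_rate_ein
        )
        if rng.random() < rate:
            gene, change, zyg, label, vclass, vtype = DEFAULT_GERMLINE_TEMPLATES[
                template_i % len(DEFAULT_GERMLINE_TEMPLATES)
            ]
            template_i += 1
            chrom, gstart, gend = gene_locus(gene, config.panel) if gene in config.panel else ("chr1", 0, 1000)
            ref, alt = ("A", "G") if vtype == "SNV" else (("ACG", "A") if vtype == "deletion" else ("A", "ACG"))
            out.append(
                VariantCall(
                    sample_id=row.sample_id, gene=gene, chrom=chrom,
                    pos=gstart + 100, ref=ref, alt=alt, variant_type=vtype,
                    variant_class=vclass,
                    depth=int(_nb(rng, config.mean_normal_depth, config.depth_dispersion, None)),
                    vaf=1.0 if zyg == "hom" else 0.5,
                    protein_change=change, origin=GERMLINE, zygosity=zyg,
                    pathogenicity=label,
                )
            )
        if rng.random() < config.germline_noise_rate:
            gene = str(rng.choice(panel_genes))
            chrom, gstart, gend = gene_locus(gene, config.panel)
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            out.append(
                VariantCall(
                    sample_id=row.sample_id, gene=gene, chrom=chrom,
                    pos=int(rng.integers(gstart + 1, gend + 1)),
                    ref=str(ref), alt=str(alt), variant_type="SNV",
                    variant_class="missense",
                    depth=int(_nb(rng, config.mean_normal_depth, config.depth_dispersion, None)),
                    vaf=0.5, origin=GERMLINE,
                    zygosity=str(rng.choice(["het", "hom"], p=[0.95, 0.05])),
                    pathogenicity=str(rng.choice(["vus", "benign"], p=[0.4, 0.6])),
                )
            )
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Per-gene driver mutations are Bernoulli per sample with the group's
    configured prevalence; background mutation counts come from the
    negative-binomial count model; every hypermutator is guaranteed at
    least one DDR-gene somatic variant, so DDR exclusion removes the
    hypermutator tail by construction. Ground truth (hypermutators, CNV
    carriers, configured prevalences, germline carriers) is recorded on the
    returned cohort.
    """
    rng = np.random.default_rng(config.seed)
    samples = _make_samples(config, rng)
    n = len(samples)
    groups = samples["group"].to_numpy()
    sample_ids = samples["sample_id"].to_numpy()

    hyper = rng.random(n) < config.hypermutator_fraction
    somatic: list[VariantCall] = []

    # driver mutations per configured prevalence
    for gene in sorted(config.prevalence):
        p_ein, p_eec = config.prevalence[gene]
        p = np.where(groups == GROUP_EEC, p_eec, p_ein)
        mutated = rng.random(n) < p
        for s in sample_ids[mutated]:
            somatic.append(_somatic_variant(rng, config, s, gene))

    # background mutations and the DDR guarantee for hypermutators; both
    # draw only from panel genes outside the prevalence map, so configured
    # per-gene prevalences stay exactly Bernoulli
    background_genes = sorted(set(config.panel) - set(config.prevalence))
    if not background_genes:
        background_genes = sorted(config.panel)
    ddr_in_panel = sorted(
        (set(DEFAULT_DDR_GENES) & set(config.panel)) - set(config.prevalence)
    ) or sorted(set(DEFAULT_DDR_GENES) & set(config.panel))
    # non-hypermutators scatter background hits over non-DDR genes: in a
    # full-size panel DDR genes are a tiny share of the footprint, whereas
    # in this condensed toy panel they would otherwise dominate and flag
    # nearly every sample as DDR-mutated
    non_ddr_background = [g for g in background_genes if g not in DEFAULT_DDR_GENES]
    if not non_ddr_background:
        non_ddr_background = background_genes
    means = np.where(hyper, config.hypermutator_mean, config.background_mean)
    ks = np.where(hyper, config.hypermutator_count_dispersion, config.count_dispersion)
    counts = np.array(
        [int(_nb(rng, m, k, None)) for m, k in zip(means, ks)]
    )
    for i, s in enumerate(sample_ids):
        c = counts[i]
        if hyper[i] and ddr_in_panel:
            somatic.append(
                _somatic_variant(rng, config, s, str(rng.choice(ddr_in_panel)))
            )
            c = max(c - 1, 0)
        pool = background_genes if hyper[i] else non_ddr_background
        for _ in range(c):
            somatic.append(
                _somatic_variant(rng, config, s, str(rng.choice(pool)))
            )

    region_depths, cnv_carriers = _region_depths(config, samples, rng)
    germ = _germline(config, samples, rng)

    truth = {
        "hypermutators": sorted(sample_ids[hyper]),
        "cnv_carriers": cnv_carriers,
        "prevalence": {g: list(p) for g, p in config.prevalence.items()},
        "germline_carriers": sorted(
            {v.sample_id for v in germ if v.pathogenicity in ("pathogenic", "likely_pathogenic")}
        ),
    }
    return Cohort(
        samples=samples, somatic=somatic, germline=germ,
        region_depths=region_depths if len(region_depths) else None,
        panel=dict(config.panel), truth=truth,
    )


def fixture_from_counts(
    group_sizes: tuple[int, int],
    gene_counts: dict[str, tuple[int, int]],
    panel: Optional[dict[str, int]] = None,
) -> Cohort:
    """Deterministic cohort reproducing exact mutated-sample counts.

    ``group_sizes`` is (n_eec, n_ein); ``gene_counts`` maps gene ->
    (mutated_eec, mutated_ein). The first k samples of each group carry one
    missense SNV in the gene (depth 500, VAF 0.30), so every downstream
    prevalence summary reproduces the input counts bit-exactly. No
    randomness is involved.
    """
    n_eec, n_ein = group_sizes
    if n_eec < 0 or n_ein < 0:
        raise ConfigurationError("group sizes must be >= 0")
    panel = panel if panel is not None else dict(DEFAULT_PANEL)
    for gene, (m_eec, m_ein) in gene_counts.items():
        if m_eec < 0 or m_ein < 0:
            raise ValidationError(f"mutated counts for {gene} must be >= 0")
        if m_eec > n_eec or m_ein > n_ein:
            raise ValidationError(
                f"mutated count for {gene} exceeds group size: "
                f"({m_eec}/{n_eec}, {m_ein}/{n_ein})"
            )
        if gene not in panel:
            panel[gene] = 2000
    rows = [
        {"sample_id": f"EEC_{i + 1:03d}", "group": GROUP_EEC,
         "grade": ["G1", "G2", "G3"][i % 3], "stage": "IA"}
        for i in range(n_eec)
    ] + [
        {"sample_id": f"EIN_{i + 1:03d}", "group": GROUP_EIN, "grade": ".", "stage": "."}
        for i in range(n_ein)
    ]
    samples = pd.DataFrame(rows, columns=["sample_id", "group", "grade", "stage"])
    somatic = []
    for gene in sorted(gene_counts):
        m_eec, m_ein = gene_counts[gene]
        chrom, gstart, _ = gene_locus(gene, panel)
        carriers = [f"EEC_{i + 1:03d}" for i in range(m_eec)] + [
            f"EIN_{i + 1:03d}" for i in range(m_ein)
        ]
        for s in carriers:
            somatic.append(
                VariantCall(
                    sample_id=s, gene=gene, chrom=chrom, pos=gstart + 101,
                    ref="C", alt="T", variant_type="SNV", variant_class="missense",
                    depth=500, vaf=0.30, exon=1, origin=SOMATIC,
                )
            )
    return Cohort(
        samples=samples, somatic=somatic, panel=panel,
        truth={"gene_counts": {g: list(c) for g, c in gene_counts.items()}},
    )


def fixture_with_germline(
    n_eec: int = 79,
    n_ein: int = 36,
    templates: Sequence[tuple[str, str, str, str, str, str]] = DEFAULT_GERMLINE_TEMPLATES,
) -> Cohort:
    """Deterministic cohort whose germline findings follow ``templates``.

    Each template is assigned to a distinct EEC sample in order, matching
    the modeled study in which every pathogenic germline finding occurred in
    a carcinoma patient.
    """
    base = fixture_from_counts((n_eec, n_ein), {})
    if len(templates) > n_eec:
        raise ValidationError("more germline templates than EEC samples")
    germ = []
    panel = dict(DEFAULT_PANEL)
    for i, (gene, change, zyg, label, vclass, vtype) in enumerate(templates):
        chrom, gstart, _ = gene_locus(gene, panel) if gene in panel else ("chr1", 0, 0)
        ref, alt = ("A", "G") if vtype == "SNV" else (
            ("ACG", "A") if vtype == "deletion" else ("A", "ACG")
        )
        germ.append(
            VariantCall(
                sample_id=f"EEC_{i + 1:03d}", gene=gene, chrom=chrom,
                pos=gstart + 100, ref=ref, alt=alt, variant_type=vtype,
                variant_class=vclass, depth=500,
                vaf=1.0 if zyg == "hom" else 0.5,
                protein_change=change, origin=GERMLINE, zygosity=zyg,
                pathogenicity=label,
            )
        )
    return Cohort(
        samples=base.samples, somatic=[], germline=germ, panel=panel,
        truth={"germline_carriers": sorted({v.sample_id for v in germ})},
    )


def spike_cnv(
    profile: pd.DataFrame,
    gene: str,
    log2_fold: float,
    affected_fraction: float = 1.0,
) -> pd.DataFrame:
    """Multiply tumor depths of a fraction of a gene's regions by 2**fold.

    Within each sample, the lowest-indexed ``round(fraction * n_regions)``
    regions of the gene are scaled; all other rows are untouched. Returns a
    modified copy.
    """
    if gene not in set(profile["gene"]):
        raise ValidationError(f"gene {gene!r} not present in profile")
    if not (0 <= affected_fraction <= 1):
        raise ValidationError("affected_fraction must be in [0, 1]")
    out = profile.copy()
    factor = 2.0 ** log2_fold
    for sample_id, idx in out.loc[out["gene"] == gene].groupby("sample_id").groups.items():
        sub = out.loc[idx].sort_values("region_index")
        k = int(round(affected_fraction * len(sub)))
        out.loc[sub.index[:k], "tumor_depth"] *= factor
    return out
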