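"""Variant data model, somatic QC filters and per-gene annotation summaries.

A :class:`VariantCall` is one observed somatic or germline variant with its
sequencing support (depth, alt-allele fraction) and functional annotation.
The QC filter implemented here is the qualifying-SNV rule used for tumor
mutational burden on high-depth targeted panels: tumor depth strictly above a
floor (default 150 reads) and variant allele fraction at or above a detection
floor (default 0.03).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .errors import ValidationError

logger = logging.getLogger(__name__)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
VARIANT_TYPES = frozenset({SNV, INSERTION, DELETION})

#: Functional classes recognized throughout the package. Unknown labels are
#: normalized to "other" by :func:`normalize_variant_class`.
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "nonframeshift_indel",
        "splice",
        "synonymous",
        "other",
    }
)

SOMATIC = "somatic"
GERMLINE = "germline"
ORIGINS = frozenset({SOMATIC, GERMLINE})
ZYGOSITIES = frozenset({"het", "hom"})

PATHOGENICITIES = frozenset({"pathogenic", "likely_pathogenic", "vus", "benign"})

_CLASS_ALIASES = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "non-sense": "nonsense",
    "stopgain": "nonsense",
    "frameshift_indel": "frameshift",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "nonframeshift": "nonframeshift_indel",
    "non-frameshift": "nonframeshift_indel",
    "in_frame_del": "nonframeshift_indel",
    "in_frame_ins": "nonframeshift_indel",
    "splice_site": "splice",
    "splicing": "splice",
    "silent": "synonymous",
}


def normalize_variant_class(label: str) -> str:
    """Map a free-form functional-class label onto the fixed vocabulary.

    Recognized aliases (MAF-style labels, hyphenated spellings) are mapped to
    their canonical class; anything else becomes ``"other"`` with a warning.
    """
    key = label.strip().lower().replace(" ", "_")
    if key in VARIANT_CLASSES:
        return key
    if key in _CLASS_ALIASES:
        return _CLASS_ALIASES[key]
    logger.warning("unknown variant class %r mapped to 'other'", label)
    return "other"


@dataclass(frozen=True)
class VariantCall:
    """One somatic or germline variant observation.

    ``pos`` is 1-based for point variants. ``vaf`` is the alt-supporting read
    fraction. ``zygosity`` and ``pathogenicity`` are meaningful for germline
    records only; pathogenicity labels arrive as input annotations
    (ClinVar-style) and are never computed here.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    variant_class: str
    depth: int = 0
    vaf: float = 0.0
    exon: Optional[int] = None
    protein_change: Optional[str] = None
    origin: str = SOMATIC
    zygosity: Optional[str] = None
    pathogenicity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth} (field: depth)")
        if not (0.0 <= self.vaf <= 1.0) or math.isnan(self.vaf):
            raise ValidationError(f"vaf must be in [0, 1], got {self.vaf} (field: vaf)")
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(
                f"variant_type must be one of {sorted(VARIANT_TYPES)}, got "
                f"{self.variant_type!r} (field: variant_type)"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"variant_class must be one of {sorted(VARIANT_CLASSES)}, got "
                f"{self.variant_class!r} (field: variant_class)"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(f"origin must be somatic/germline, got {self.origin!r} (field: origin)")
        if self.zygosity is not None and self.zygosity not in ZYGOSITIES:
            raise ValidationError(f"zygosity must be het/hom, got {self.zygosity!r} (field: zygosity)")
        if self.ref and self.alt:
            self._check_type_consistency()

    def _check_type_consistency(self) -> None:
        lr, la = len(self.ref), len(self.alt)
        if self.variant_type == SNV and not (lr == la == 1):
            raise ValidationError(
                f"SNV requires single-base ref/alt, got {self.ref!r}>{self.alt!r} (field: variant_type)"
            )
        if self.variant_type == INSERTION and la <= lr:
            raise ValidationError(
                f"insertion requires len(alt) > len(ref), got {self.ref!r}>{self.alt!r} (field: variant_type)"
            )
        if self.variant_type == DELETION and lr <= la:
            raise ValidationError(
                f"deletion requires len(ref) > len(alt), got {self.ref!r}>{self.alt!r} (field: variant_type)"
            )

    def with_(self, **kwargs) -> "VariantCall":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FilterPolicy:
    """Qualifying-variant rule for TMB.

    ``min_depth_exclusive`` — depth must be *strictly greater* than this.
    ``min_vaf_inclusive`` — VAF must be greater than or equal to this.
    ``snv_only_for_tmb`` — when true (default) indels never qualify; a flag
    for sensitivity analyses that count indels as well.
    """

    min_depth_exclusive: int = 150
    min_vaf_inclusive: float = 0.03
    snv_only_for_tmb: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_exclusive < 0:
            raise ValidationError(
                f"min_depth_exclusive must be >= 0, got {self.min_depth_exclusive}"
            )
        if not (0.0 <= self.min_vaf_inclusive <= 1.0):
            raise ValidationError(
                f"min_vaf_inclusive must be in [0, 1], got {self.min_vaf_inclusive}"
            )


def filter_qualifying_snvs(
    variants: Sequence[VariantCall], policy: FilterPolicy = FilterPolicy()
) -> list[VariantCall]:
    """Return the variants that qualify for TMB counting, in input order.

    A record qualifies when it is an SNV (unless ``snv_only_for_tmb`` is
    off), its depth exceeds ``min_depth_exclusive`` strictly, and its VAF is
    at least ``min_vaf_inclusive``.
    """
    out = []
    for v in variants:
        if policy.snv_only_for_tmb and v.variant_type != SNV:
            continue
        if v.depth <= policy.min_depth_exclusive:
            continue
        if v.vaf < policy.min_vaf_inclusive:
            continue
        out.append(v)
    return out


@dataclass(frozen=True)
class ExonFraction:
    """Share of a gene's variants that fall in one exon.

    ``fraction`` is ``None`` when the gene has no variants at all (an
    undefined fraction, deliberately not a division error).
    """

    count_in_exon: int
    total: int
    fraction: Optional[float]


def exon_fraction(variants: Iterable[VariantCall], gene: str, exon: int) -> ExonFraction:
    """Fraction of ``gene``'s variants annotated to ``exon``.

    Variants with unknown exon count toward the denominator only.
    """
    total = 0
    hit = 0
    for v in variants:
        if v.gene != gene:
            continue
        total += 1
        if v.exon == exon:
            hit += 1
    return ExonFraction(hit, total, hit / total if total else None)


def recurrent_variants(
    variants: Iterable[VariantCall], gene: str
) -> list[tuple[str, int, float]]:
    """Rank a gene's protein changes by recurrence.

    Returns ``(protein_change, count, share)`` triples sorted by descending
    count, ties broken lexicographically by protein change. ``share`` is
    taken over *all* variants of the gene, so shares need not sum to 1 when
    some records lack a protein-change annotation.
    """
    total = 0
    counts: Counter[str] = Counter()
    for v in variants:
        if v.gene != gene:
            continue
        total += 1
        if v.protein_change:
            counts[v.protein_change] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(pc, n, n / total) for pc, n in ranked]


def variant_class_breakdown(variants: Iterable[VariantCall], gene: str) -> dict[str, float]:
    """Share of each functional class among a gene's variants.

    Only non-empty classes appear; shares sum to 1 for non-empty input.
    """
    counts: Counter[str] = Counter(v.variant_class for v in variants if v.gene == gene)
    total = sum(counts.values())
    return {cls: n / total for cls, n in sorted(counts.items())}
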