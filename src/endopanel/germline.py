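"""Rule-based germline pathogenic-variant screening.

Variants arrive with ClinVar-style pathogenicity annotations; screening
keeps pathogenic and likely-pathogenic records, splits them into
Lynch-syndrome (MLH1/MSH2/MSH6/PMS2) versus non-Lynch predisposition genes,
and applies recessive-gene zygosity handling: in genes whose phenotype
requires biallelic inactivation (MUTYH by default) a heterozygous finding
is retained as a carrier state but is not actionable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .variants import VariantCall

LYNCH_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})
DEFAULT_RECESSIVE_GENES = frozenset({"MUTYH"})

_TRUNCATING_CLASSES = {"nonsense", "frameshift", "splice"}

_PATHOGENICITY_ALIASES = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "uncertain significance": "vus",
    "vus": "vus",
    "benign": "benign",
    "likely benign": "benign",
    "likely_benign": "benign",
}


def normalize_pathogenicity(label: str) -> str:
    key = label.strip().lower().replace("-", " ")
    key = _PATHOGENICITY_ALIASES.get(key, _PATHOGENICITY_ALIASES.get(key.replace(" ", "_"), None))
    if key is None:
        raise ValidationError(f"unknown pathogenicity label (field: pathogenicity): {label!r}")
    return key


@dataclass(frozen=True)
class GeneSets:
    """Gene sets steering the screen.

    ``lynch`` — mismatch-repair genes defining Lynch syndrome.
    ``recessive`` — genes whose phenotype requires biallelic hits; the sets
    need not be disjoint.
    """

    lynch: frozenset[str] = LYNCH_GENES
    recessive: frozenset[str] = DEFAULT_RECESSIVE_GENES

    def __post_init__(self) -> None:
        if not self.lynch:
            raise ValidationError("lynch gene set must be non-empty")


@dataclass(frozen=True)
class GermlineFinding:
    sample_id: str
    gene: str
    base_change: str
    zygosity: str
    pathogenicity: str  # pathogenic / likely_pathogenic
    syndrome_class: str  # lynch / non_lynch
    biallelic_required: bool
    actionable: bool


def screen_germline(
    variants: Sequence[VariantCall],
    sets: GeneSets = GeneSets(),
    upgrade_truncating: bool = False,
) -> list[GermlineFinding]:
    """Screen annotated germline variants into reportable findings.

    Retains pathogenic/likely-pathogenic records only. With
    ``upgrade_truncating`` (off by default), unannotated truncating variants
    (nonsense/frameshift/canonical splice) are upgraded to likely
    pathogenic before screening.
    """
    findings = []
    for v in variants:
        label = v.pathogenicity
        if label is None:
            if upgrade_truncating and v.variant_class in _TRUNCATING_CLASSES:
                label = "likely_pathogenic"
            else:
                continue
        else:
            label = normalize_pathogenicity(label)
        if label not in {"pathogenic", "likely_pathogenic"}:
            continue
        if v.zygosity is None:
            raise ValidationError(
                f"germline variant in {v.gene} lacks zygosity (field: zygosity)"
            )
        recessive = v.gene in sets.recessive
        findings.append(
            GermlineFinding(
                sample_id=v.sample_id,
                gene=v.gene,
                base_change=v.protein_change or f"{v.ref}>{v.alt}",
                zygosity=v.zygosity,
                pathogenicity=label,
                syndrome_class="lynch" if v.gene in sets.lynch else "non_lynch",
                biallelic_required=recessive,
                actionable=not (recessive and v.zygosity == "het"),
            )
        )
    findings.sort(key=lambda f: (f.gene, f.sample_id, f.base_change))
    return findings


@dataclass(frozen=True)
class GermlineSummary:
    n_patients: int
    n_carriers: int
    overall_carrier_rate: float  # fraction of all patients with >=1 finding
    n_lynch_carriers_eec: int
    n_eec: int
    lynch_rate_eec: float  # fraction of EEC patients with a Lynch-gene finding
    per_gene_counts: dict[str, int]
    findings: pd.DataFrame


def germline_summary(findings: Sequence[GermlineFinding], samples: pd.DataFrame) -> GermlineSummary:
    """Carrier rates and a findings listing for the cohort.

    The overall carrier rate counts each patient once however many findings
    they have; the Lynch rate is restricted to EEC patients, the group in
    which mismatch-repair screening is clinically decisive.
    """
    n_patients = len(samples)
    eec = set(samples.loc[samples["group"] == "EEC", "sample_id"])
    carriers = {f.sample_id for f in findings}
    lynch_eec = {
        f.sample_id for f in findings if f.syndrome_class == "lynch" and f.sample_id in eec
    }
    per_gene: dict[str, int] = {}
    for f in findings:
        per_gene[f.gene] = per_gene.get(f.gene, 0) + 1
    table = pd.DataFrame(
        [
            {
                "gene": f.gene,
                "sample_id": f.sample_id,
                "base_change": f.base_change,
                "zygosity": f.zygosity,
                "pathogenicity": f.pathogenicity,
                "syndrome_class": f.syndrome_class,
                "actionable": f.actionable,
            }
            for f in sorted(findings, key=lambda f: (f.gene, f.sample_id))
        ],
        columns=[
            "gene", "sample_id", "base_change", "zygosity",
            "pathogenicity", "syndrome_class", "actionable",
        ],
    )
    return GermlineSummary(
        n_patients=n_patients,
        n_carriers=len(carriers),
        overall_carrier_rate=len(carriers) / n_patients if n_patients else 0.0,
        n_lynch_carriers_eec=len(lynch_eec),
        n_eec=len(eec),
        lynch_rate_eec=len(lynch_eec) / len(eec) if eec else 0.0,
        per_gene_counts=dict(sorted(per_gene.items())),
        findings=table,
    )
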