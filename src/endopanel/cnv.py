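"""Region-based tumor/normal depth-ratio CNV calling.

Each gene's panel footprint is divided into regions; the log2 ratio (LRR) of
mean tumor depth to matched-normal depth is computed per region, each region
is classified as amplified (LRR above a positive threshold), deleted (LRR
below a negative threshold) or neutral, and a gene receives a call when one
non-neutral class holds a strict majority (> 70% by default) of the gene's
evaluable regions.

Regions whose normal depth falls below a floor (default 20 reads) are not
evaluable and are excluded from both the numerator and the denominator of
the majority rule, so near-zero normal coverage can never manufacture an
extreme ratio. No cross-sample normalization or GC correction is applied:
the caller is a pure paired tumor/normal ratio method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

AMP = "amplification"
DEL = "deletion"
NONE = "none"
NEUTRAL = "neutral"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class CnvThresholds:
    """Thresholds of the depth-ratio caller.

    ``amp_lrr``/``del_lrr`` — strict LRR bounds for amplified/deleted
    regions. The deletion bound defaults to -0.5: a positive printed cutoff
    for deletions would classify every slightly-below-neutral region as
    deleted, so the deletion bound mirrors the amplification side as a
    negative threshold (configurable, see the methods note).
    ``majority`` — fraction of evaluable regions one class must *strictly*
    exceed for a gene-level call. ``min_normal_depth`` — evaluability floor
    on the matched-normal mean depth.
    """

    amp_lrr: float = 0.35
    del_lrr: float = -0.5
    majority: float = 0.70
    min_normal_depth: float = 20.0

    def __post_init__(self) -> None:
        if not (self.amp_lrr > 0 > self.del_lrr):
            raise ValidationError(
                f"require amp_lrr > 0 > del_lrr, got {self.amp_lrr}, {self.del_lrr}"
            )
        if not (0 < self.majority < 1):
            raise ValidationError(f"majority must be in (0, 1), got {self.majority}")
        if self.min_normal_depth < 0:
            raise ValidationError("min_normal_depth must be >= 0")


@dataclass(frozen=True)
class RegionDepthPair:
    """Mean tumor and matched-normal depth over one region of a gene.

    Coordinates follow the BED convention: 0-based, half-open.
    """

    gene: str
    region_index: int
    chrom: str
    start: int
    end: int
    tumor_depth: float
    normal_depth: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end}) (field: start)"
            )
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValidationError("depths must be >= 0 (field: tumor_depth/normal_depth)")


@dataclass(frozen=True)
class GeneCnvCall:
    """Per-gene verdict with the supporting region tally.

    ``n_regions`` counts evaluable regions only; ``n_total`` includes
    non-evaluable ones. ``supporting_fraction`` is max(n_amp, n_del) over
    evaluable regions, or None when nothing was evaluable.
    """

    gene: str
    sample_id: str
    call: str  # amplification / deletion / none
    n_regions: int
    n_amp: int
    n_del: int
    supporting_fraction: Optional[float]
    n_total: int = 0
    reason: Optional[str] = None


def region_lrr(pair: RegionDepthPair, thresholds: CnvThresholds = CnvThresholds()) -> float:
    """log2(tumor/normal) for one region, NaN when not evaluable.

    A region is evaluable when normal depth >= min_normal_depth and tumor
    depth > 0; degenerate depths yield NaN, never infinities.
    """
    if pair.normal_depth < thresholds.min_normal_depth or pair.tumor_depth <= 0:
        return math.nan
    return math.log2(pair.tumor_depth / pair.normal_depth)


def classify_region(lrr: float, thresholds: CnvThresholds = CnvThresholds()) -> str:
    """Classify one region's LRR; both threshold comparisons are strict."""
    if math.isnan(lrr):
        return NOT_EVALUABLE
    if lrr > thresholds.amp_lrr:
        return "amp"
    if lrr < thresholds.del_lrr:
        return "del"
    return NEUTRAL


def call_gene_cnv(
    regions: Sequence[RegionDepthPair],
    thresholds: CnvThresholds = CnvThresholds(),
    sample_id: str = "",
) -> GeneCnvCall:
    """Call one gene in one sample from its region depth pairs.

    The gene is amplified (deleted) when the amplified (deleted) fraction of
    *evaluable* regions strictly exceeds the majority threshold; an
    exactly-at-threshold fraction never produces a call.
    """
    if not regions:
        raise ValidationError("call_gene_cnv requires at least one region")
    genes = {r.gene for r in regions}
    if len(genes) != 1:
        raise ValidationError(f"regions span multiple genes: {sorted(genes)}")
    (gene,) = genes
    classes = [classify_region(region_lrr(r, thresholds), thresholds) for r in regions]
    return call_from_classifications(gene, sample_id, classes, thresholds)


def call_from_classifications(
    gene: str,
    sample_id: str,
    classifications: Sequence[str],
    thresholds: CnvThresholds = CnvThresholds(),
) -> GeneCnvCall:
    """Majority rule over pre-classified regions (amp/del/neutral/not_evaluable)."""
    n_total = len(classifications)
    evaluable = [c for c in classifications if c != NOT_EVALUABLE]
    n_amp = sum(c == "amp" for c in evaluable)
    n_del = sum(c == "del" for c in evaluable)
    n_eval = len(evaluable)
    if n_eval == 0:
        return GeneCnvCall(
            gene, sample_id, NONE, 0, 0, 0, None, n_total, reason="no evaluable regions"
        )
    frac = max(n_amp, n_del) / n_eval
    call = NONE
    if n_amp / n_eval > thresholds.majority:
        call = AMP
    elif n_del / n_eval > thresholds.majority:
        call = DEL
    return GeneCnvCall(gene, sample_id, call, n_eval, n_amp, n_del, frac, n_total)


def call_cohort(
    region_depths: pd.DataFrame, thresholds: CnvThresholds = CnvThresholds()
) -> list[GeneCnvCall]:
    """Call every (sample, gene) present in a long-format region-depth table.

    Expects columns sample_id, gene, region_index, chrom, start, end,
    tumor_depth, normal_depth. Vectorized: LRR and region classes are
    computed on whole columns, then aggregated per sample and gene.
    """
    df = region_depths
    t = df["tumor_depth"].to_numpy(float)
    n = df["normal_depth"].to_numpy(float)
    evaluable = (n >= thresholds.min_normal_depth) & (t > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.where(evaluable, np.log2(np.where(evaluable, t, 1) / np.where(evaluable, n, 1)), np.nan)
    work = pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "gene": df["gene"].to_numpy(),
            "evaluable": evaluable,
            "amp": evaluable & (lrr > thresholds.amp_lrr),
            "del": evaluable & (lrr < thresholds.del_lrr),
        }
    )
    agg = work.groupby(["sample_id", "gene"], sort=True).agg(
        n_total=("evaluable", "size"),
        n_eval=("evaluable", "sum"),
        n_amp=("amp", "sum"),
        n_del=("del", "sum"),
    )
    out = []
    for (sample_id, gene), row in agg.iterrows():
        n_eval, n_amp, n_del = int(row.n_eval), int(row.n_amp), int(row.n_del)
        if n_eval == 0:
            out.append(
                GeneCnvCall(
                    gene, sample_id, NONE, 0, 0, 0, None, int(row.n_total),
                    reason="no evaluable regions",
                )
            )
            continue
        call = NONE
        if n_amp / n_eval > thresholds.majority:
            call = AMP
        elif n_del / n_eval > thresholds.majority:
            call = DEL
        out.append(
            GeneCnvCall(
                gene, sample_id, call, n_eval, n_amp, n_del,
                max(n_amp, n_del) / n_eval, int(row.n_total),
            )
        )
    return out


@dataclass(frozen=True)
class CnaSummary:
    """Cohort-level copy-number alteration summary."""

    n_samples: int
    n_affected: int
    affected_fraction: float
    per_sample_counts: dict[str, int]
    median_cnas_per_sample: float
    cna_range: tuple[int, int]
    per_gene: pd.DataFrame  # gene, amp, del, plus per-group carrier counts/shares


def cna_summary(
    calls: Iterable[GeneCnvCall],
    samples: pd.DataFrame,
) -> CnaSummary:
    """Summarize non-none calls across a cohort.

    ``samples`` is the sample sheet (sample_id, group, ...); samples with no
    calls count as zero CNAs. Group shares of a gene's carriers are taken
    against the carrier count, matching how recurrent CNAs are usually
    reported (e.g. "19/20 carriers were carcinomas").
    """
    sample_ids = list(samples["sample_id"])
    groups = dict(zip(samples["sample_id"], samples["group"]))
    counts = {s: 0 for s in sample_ids}
    gene_rows: dict[tuple[str, str], dict[str, int]] = {}
    for c in calls:
        if c.call == NONE:
            continue
        counts[c.sample_id] += 1
        key = (c.gene, c.call)
        row = gene_rows.setdefault(key, {})
        g = groups[c.sample_id]
        row[g] = row.get(g, 0) + 1
    per_gene = []
    group_labels = sorted(set(groups.values()))
    for (gene, call), by_group in sorted(gene_rows.items()):
        n_carriers = sum(by_group.values())
        row = {"gene": gene, "call": call, "n_carriers": n_carriers}
        for g in group_labels:
            row[f"n_{g}"] = by_group.get(g, 0)
            row[f"share_{g}"] = by_group.get(g, 0) / n_carriers
        per_gene.append(row)
    per_gene_df = pd.DataFrame(
        per_gene,
        columns=["gene", "call", "n_carriers"]
        + [c for g in group_labels for c in (f"n_{g}", f"share_{g}")],
    )
    if len(per_gene_df):
        per_gene_df = per_gene_df.sort_values(
            ["n_carriers", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    vals = np.array(list(counts.values())) if counts else np.array([0])
    n_aff = int((vals > 0).sum())
    return CnaSummary(
        n_samples=len(sample_ids),
        n_affected=n_aff,
        affected_fraction=n_aff / len(sample_ids) if sample_ids else 0.0,
        per_sample_counts=counts,
        median_cnas_per_sample=float(np.median(vals)),
        cna_range=(int(vals.min()), int(vals.max())),
        per_gene=per_gene_df,
    )


def cnv_matrix(calls: Iterable[GeneCnvCall], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Genes x samples matrix with values A (amplified), D (deleted), '.'."""
    code = {AMP: "A", DEL: "D"}
    cells: dict[str, dict[str, str]] = {}
    for c in calls:
        if c.call in code:
            cells.setdefault(c.gene, {})[c.sample_id] = code[c.call]
    genes = sorted(cells)
    mat = pd.DataFrame(".", index=genes, columns=list(sample_ids))
    for gene, row in cells.items():
        for s, v in row.items():
            mat.loc[gene, s] = v
    mat.index.name = "gene"
    return mat
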