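"""End-to-end orchestration: read inputs, run every stage, write reports.

``run_pipeline`` produces a TMB report, group TMB comparisons (with and
without DDR-mutated samples), per-gene CNV calls and a cohort CNA matrix, a
prevalence/association report, co-mutation reports, germline findings and
carrier rates, plus a machine-readable manifest (config hash, version,
per-stage record counts). Reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cnv import CnvThresholds, call_cohort, cna_summary, cnv_matrix
from .cohort import Cohort
from .errors import ConfigurationError
from .germline import GeneSets, germline_summary, screen_germline
from .io import (
    fmt_float,
    read_panel,
    read_region_depths,
    read_sample_sheet,
    read_variants,
    read_yaml_config,
    write_json,
)
from .stats import differential_screen, comutation, oncoprint_matrix
from .tmb import DdrGeneSet, DEFAULT_HYPERMUTATION_THRESHOLD, compare_tmb, tmb_report
from .variants import FilterPolicy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, policies and thresholds for a full run."""

    sample_sheet: Path
    somatic_variants: Path
    output_dir: Path
    germline_variants: Optional[Path] = None
    region_depths: Optional[Path] = None
    panel: Optional[Path] = None
    panel_mb: Optional[float] = None  # overrides the panel file footprint
    extrapolation_factor: float = 1.0
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    cnv_thresholds: CnvThresholds = field(default_factory=CnvThresholds)
    ddr_genes: DdrGeneSet = field(default_factory=DdrGeneSet)
    gene_sets: GeneSets = field(default_factory=GeneSets)
    hypermutation_threshold: int = DEFAULT_HYPERMUTATION_THRESHOLD
    alpha: float = 0.05
    correction: str = "none"
    min_mutated: int = 1
    comutation_pairs: Sequence[tuple[str, str]] = (("PTEN", "PIK3CA"), ("PTEN", "PIK3R1"))
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Build a config from a YAML/JSON mapping; flags mirror field names."""
        raw = read_yaml_config(path)
        base = Path(path).parent

        def p(key):
            return (base / raw[key]) if key in raw and raw[key] else None

        kwargs = {}
        for key in ("sample_sheet", "somatic_variants", "output_dir",
                    "germline_variants", "region_depths", "panel"):
            if p(key) is not None:
                kwargs[key] = p(key)
        for key in ("panel_mb", "extrapolation_factor", "hypermutation_threshold",
                    "alpha", "correction", "min_mutated", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filter_policy" in raw:
            kwargs["filter_policy"] = FilterPolicy(**raw["filter_policy"])
        if "cnv_thresholds" in raw:
            kwargs["cnv_thresholds"] = CnvThresholds(**raw["cnv_thresholds"])
        if "ddr_genes" in raw:
            kwargs["ddr_genes"] = DdrGeneSet(frozenset(raw["ddr_genes"]))
        if "gene_sets" in raw:
            kwargs["gene_sets"] = GeneSets(
                lynch=frozenset(raw["gene_sets"].get("lynch", GeneSets().lynch)),
                recessive=frozenset(raw["gene_sets"].get("recessive", GeneSets().recessive)),
            )
        if "comutation_pairs" in raw:
            kwargs["comutation_pairs"] = [tuple(pair) for pair in raw["comutation_pairs"]]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return asdict(o)

        fields = asdict(self)
        fields.pop("output_dir", None)  # hash the analytic config, not the destination
        payload = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_inputs(config: PipelineConfig) -> Cohort:
    """Load and cross-validate all input files into a cohort bundle.

    Referential integrity (variant and depth records against the sample
    sheet, genes against the panel when one is given) is enforced; parse
    errors carry file and line information.
    """
    samples = read_sample_sheet(config.sample_sheet)
    somatic = read_variants(config.somatic_variants)
    germline = read_variants(config.germline_variants) if config.germline_variants else []
    depths = read_region_depths(config.region_depths) if config.region_depths else None
    panel = read_panel(config.panel) if config.panel else None
    if panel is not None:
        known = set(panel)
        for v in somatic:
            if v.gene not in known:
                raise ConfigurationError(
                    f"somatic variant gene {v.gene!r} not in panel definition"
                )
    return Cohort(
        samples=samples, somatic=somatic, germline=germline,
        region_depths=depths, panel=panel,
    )


def _effective_panel_mb(config: PipelineConfig, cohort: Cohort) -> float:
    if config.panel_mb is not None:
        if config.panel_mb <= 0:
            raise ConfigurationError(f"panel_mb must be > 0, got {config.panel_mb}")
        return config.panel_mb
    if cohort.panel:
        return sum(cohort.panel.values()) / 1e6
    from .simulate import DEFAULT_PANEL

    logger.warning(
        "no panel footprint given; using the bundled toy panel (%.4f Mb)",
        sum(DEFAULT_PANEL.values()) / 1e6,
    )
    return sum(DEFAULT_PANEL.values()) / 1e6


def run_pipeline(config: PipelineConfig, cohort: Optional[Cohort] = None) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths.

    A pre-loaded cohort may be passed to skip re-reading inputs (used by the
    simulator round-trip and the tests).
    """
    t_start = time.time()
    if cohort is None:
        cohort = read_inputs(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_counts: dict[str, int] = {}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.time()

    # --- TMB ------------------------------------------------------------
    t0 = stage("tmb")
    panel_mb = _effective_panel_mb(config, cohort)
    by_sample = cohort.somatic_by_sample()
    results = tmb_report(
        by_sample, panel_mb, config.filter_policy, config.extrapolation_factor,
        config.ddr_genes, config.hypermutation_threshold,
    )
    tmb_df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "qualifying_snv_count": r.qualifying_snv_count,
                "panel_mb": fmt_float(r.panel_mb),
                "tmb": fmt_float(r.tmb),
                "hypermutated": r.hypermutated,
                "ddr_mutated": r.ddr_mutated,
            }
            for r in sorted(results, key=lambda r: r.sample_id)
        ]
    )
    outputs["tmb_report"] = out_dir / "tmb_report.tsv"
    tmb_df.to_csv(outputs["tmb_report"], sep="\t", index=False)
    comparisons = {}
    groups = cohort.groups
    for exclude in (False, True):
        try:
            cmp = compare_tmb(results, groups, exclude_ddr=exclude)
            comparisons["excluding_ddr" if exclude else "all_samples"] = {
                "medians": {g: float(fmt_float(m)) for g, m in cmp.medians.items()},
                "n": cmp.n,
                "p_two_sided": float(fmt_float(cmp.p_two_sided)),
                "test": cmp.test,
            }
        except Exception as exc:  # degenerate cohorts (empty group)
            comparisons["excluding_ddr" if exclude else "all_samples"] = {
                "error": str(exc)
            }
    outputs["tmb_comparison"] = out_dir / "tmb_comparison.json"
    write_json(comparisons, outputs["tmb_comparison"])
    stage_counts["tmb"] = len(results)
    timings["tmb"] = time.time() - t0

    # --- CNV ------------------------------------------------------------
    t0 = stage("cnv")
    if cohort.region_depths is not None and len(cohort.region_depths):
        calls = call_cohort(cohort.region_depths, config.cnv_thresholds)
        calls_df = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id, "gene": c.gene, "call": c.call,
                    "n_regions": c.n_regions, "n_amp": c.n_amp, "n_del": c.n_del,
                    "supporting_fraction": fmt_float(c.supporting_fraction)
                    if c.supporting_fraction is not None else ".",
                }
                for c in calls
            ]
        )
        outputs["cnv_calls"] = out_dir / "cnv_calls.tsv"
        calls_df.to_csv(outputs["cnv_calls"], sep="\t", index=False)
        outputs["cnv_matrix"] = out_dir / "cnv_matrix.tsv"
        cnv_matrix(calls, cohort.sample_ids).to_csv(outputs["cnv_matrix"], sep="\t")
        summ = cna_summary(calls, cohort.samples)
        stage_counts["cnv_calls"] = sum(c.call != "none" for c in calls)
        outputs["cnv_summary"] = out_dir / "cnv_summary.json"
        write_json(
            {
                "n_samples": summ.n_samples,
                "n_affected": summ.n_affected,
                "affected_fraction": float(fmt_float(summ.affected_fraction)),
                "median_cnas_per_sample": summ.median_cnas_per_sample,
                "cna_range": list(summ.cna_range),
            },
            outputs["cnv_summary"],
        )
    else:
        stage_counts["cnv_calls"] = 0
    timings["cnv"] = time.time() - t0

    # --- cohort statistics ---------------------------------------------
    t0 = stage("stats")
    screen = differential_screen(
        cohort, min_mutated=config.min_mutated, alpha=config.alpha,
        correction=config.correction,
    )
    stats_df = screen.results.copy()
    for col in ("percentage", "statistic", "p_two_sided", "p_adjusted"):
        stats_df[col] = stats_df[col].map(
            lambda x: fmt_float(x) if pd.notna(x) else "."
        )
    outputs["stats_report"] = out_dir / "prevalence_stats.tsv"
    stats_df.to_csv(outputs["stats_report"], sep="\t", index=False)
    outputs["oncoprint"] = out_dir / "oncoprint_matrix.tsv"
    oncoprint_matrix(cohort).to_csv(outputs["oncoprint"], sep="\t")
    stage_counts["stats_genes"] = len(stats_df)

    comut_rows = []
    for ga, gb in config.comutation_pairs:
        r = comutation(cohort, ga, gb)
        comut_rows.append(
            {
                "gene_a": ga, "gene_b": gb,
                "co_mutated_eec": r.n_co_eec, "co_mutated_ein": r.n_co_ein,
                "share_eec": fmt_float(r.share_eec), "share_ein": fmt_float(r.share_ein),
                "test_used": r.association.test_used,
                "p_two_sided": fmt_float(r.association.p_two_sided),
            }
        )
    outputs["comutation"] = out_dir / "comutation.tsv"
    pd.DataFrame(
        comut_rows,
        columns=["gene_a", "gene_b", "co_mutated_eec", "co_mutated_ein",
                 "share_eec", "share_ein", "test_used", "p_two_sided"],
    ).to_csv(outputs["comutation"], sep="\t", index=False)
    timings["stats"] = time.time() - t0

    # --- germline -------------------------------------------------------
    t0 = stage("germline")
    findings = screen_germline(cohort.germline, config.gene_sets)
    summary = germline_summary(findings, cohort.samples)
    outputs["germline_findings"] = out_dir / "germline_findings.tsv"
    summary.findings.to_csv(outputs["germline_findings"], sep="\t", index=False)
    outputs["germline_rates"] = out_dir / "germline_rates.json"
    write_json(
        {
            "n_patients": summary.n_patients,
            "n_carriers": summary.n_carriers,
            "overall_carrier_rate": float(fmt_float(summary.overall_carrier_rate)),
            "n_lynch_carriers_eec": summary.n_lynch_carriers_eec,
            "n_eec": summary.n_eec,
            "lynch_rate_eec": float(fmt_float(summary.lynch_rate_eec)),
            "per_gene_counts": summary.per_gene_counts,
        },
        outputs["germline_rates"],
    )
    stage_counts["germline_findings"] = len(findings)
    timings["germline"] = time.time() - t0

    # --- manifest -------------------------------------------------------
    outputs["manifest"] = out_dir / "manifest.json"
    write_json(
        {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "n_samples": len(cohort.samples),
            "n_somatic_variants": len(cohort.somatic),
            "n_germline_variants": len(cohort.germline),
            "stage_record_counts": stage_counts,
            "outputs": {k: str(v.name) for k, v in outputs.items() if k != "manifest"},
        },
        outputs["manifest"],
    )
    logger.info("pipeline finished in %.2fs", time.time() - t_start)
    return outputs
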