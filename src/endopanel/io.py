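"""Readers and writers for the pipeline's interchange formats.

All tables are UTF-8 TSV with mandatory headers; missing values are encoded
as ".". Region-depth coordinates follow the BED convention (0-based,
half-open). Floats in reports are formatted at 6 significant digits so that
reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .variants import VariantCall, normalize_variant_class

PathLike = Union[str, Path]

MISSING = "."

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_type",
    "variant_class", "exon", "protein_change", "depth", "vaf", "origin",
    "zygosity", "pathogenicity",
]

REGION_DEPTH_COLUMNS = [
    "chrom", "start", "end", "gene", "region_index",
    "tumor_depth", "normal_depth", "sample_id",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "grade", "stage"]


def fmt_float(x: float) -> str:
    """Stable 6-significant-digit float formatting for report files."""
    return f"{x:.6g}"


def _check_header(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    # pandas mangles duplicate headers, so inspect the raw first line too
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = fh.readline().rstrip("\n").split("\t")
        if len(set(raw)) != len(raw):
            dupes = sorted({c for c in raw if raw.count(c) > 1})
            raise SchemaError(f"{path}: duplicate header column(s): {dupes}")
    except OSError:
        pass
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")


def variant_to_row(v: VariantCall) -> dict:
    return {
        "sample_id": v.sample_id, "gene": v.gene, "chrom": v.chrom, "pos": v.pos,
        "ref": v.ref, "alt": v.alt, "variant_type": v.variant_type,
        "variant_class": v.variant_class,
        "exon": v.exon if v.exon is not None else MISSING,
        "protein_change": v.protein_change if v.protein_change else MISSING,
        "depth": v.depth, "vaf": fmt_float(v.vaf), "origin": v.origin,
        "zygosity": v.zygosity if v.zygosity else MISSING,
        "pathogenicity": v.pathogenicity if v.pathogenicity else MISSING,
    }


def _opt(value, cast=str):
    s = str(value)
    if s in (MISSING, "", "nan", "None"):
        return None
    return cast(s)


def write_variants(variants: Iterable[VariantCall], path: PathLike) -> None:
    df = pd.DataFrame([variant_to_row(v) for v in variants], columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variants(path: PathLike) -> list[VariantCall]:
    """Read a variant table; row errors are reported with line numbers."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_header(df, [c for c in VARIANT_COLUMNS if c not in ("exon", "protein_change", "zygosity", "pathogenicity")], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        d = row._asdict()
        try:
            out.append(
                VariantCall(
                    sample_id=d["sample_id"], gene=d["gene"], chrom=d["chrom"],
                    pos=int(d["pos"]), ref=d["ref"], alt=d["alt"],
                    variant_type=d["variant_type"],
                    variant_class=normalize_variant_class(d["variant_class"]),
                    exon=_opt(d.get("exon", MISSING), int),
                    protein_change=_opt(d.get("protein_change", MISSING)),
                    depth=int(d["depth"]), vaf=float(d["vaf"]),
                    origin=d.get("origin", "somatic"),
                    zygosity=_opt(d.get("zygosity", MISSING)),
                    pathogenicity=_opt(d.get("pathogenicity", MISSING)),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise SchemaError(f"{path}: line {i}: {exc}") from exc
    return out


def write_sample_sheet(samples: pd.DataFrame, path: PathLike) -> None:
    samples[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_header(df, SAMPLE_SHEET_COLUMNS, path)
    return df[SAMPLE_SHEET_COLUMNS]


def write_region_depths(depths: pd.DataFrame, path: PathLike) -> None:
    df = depths[REGION_DEPTH_COLUMNS].copy()
    for col in ("tumor_depth", "normal_depth"):
        df[col] = df[col].map(fmt_float)
    df.to_csv(path, sep="\t", index=False)


def read_region_depths(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_header(df, REGION_DEPTH_COLUMNS, path)
    try:
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"].astype(int),
                "end": df["end"].astype(int),
                "gene": df["gene"],
                "region_index": df["region_index"].astype(int),
                "tumor_depth": df["tumor_depth"].astype(float),
                "normal_depth": df["normal_depth"].astype(float),
                "sample_id": df["sample_id"],
            }
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    bad = out["start"] >= out["end"]
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(f"{path}: line {line}: start must be < end")
    return out


def write_panel(panel: dict[str, int], path: PathLike) -> None:
    pd.DataFrame(
        sorted(panel.items()), columns=["gene", "target_bp"]
    ).to_csv(path, sep="\t", index=False)


def read_panel(path: PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_header(df, ["gene", "target_bp"], path)
    return dict(zip(df["gene"], df["target_bp"].astype(int)))


def write_truth(truth: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml_config(path: PathLike) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return data


# -- minimal VCF reader --------------------------------------------------------

DEFAULT_VCF_FIELD_MAP = {"depth": "FORMAT/DP", "vaf": "FORMAT/AF"}


def read_vcf_variants(
    path: PathLike,
    gene_of: Optional[dict[str, str]] = None,
    field_map: Optional[dict[str, str]] = None,
    origin: str = "somatic",
) -> list[VariantCall]:
    """Read a minimal single-sample VCF into variant records.

    ``field_map`` declares where depth and allele fraction live, e.g.
    ``{"depth": "FORMAT/DP", "vaf": "FORMAT/AF"}`` or ``INFO/...`` keys.
    ``gene_of`` maps chromosome names to gene symbols when the VCF carries
    no gene annotation (panel data is usually per-gene already); a ``GENE``
    INFO tag takes precedence. Multi-allelic records must be pre-split to
    one alt per record.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    fm = dict(DEFAULT_VCF_FIELD_MAP, **(field_map or {}))
    vcf = VCF(str(path))
    if len(vcf.samples) > 1:
        raise SchemaError(f"{path}: expected a single-sample VCF, got {len(vcf.samples)}")
    sample_id = vcf.samples[0] if vcf.samples else "sample"

    def fetch(record, field_spec):
        scope, key = field_spec.split("/", 1)
        if scope == "INFO":
            return record.INFO.get(key)
        val = record.format(key)
        if val is None:
            return None
        return val[0][0] if hasattr(val[0], "__len__") else val[0]

    out = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise SchemaError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; pre-split required"
            )
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) == len(alt) == 1:
            vtype = "SNV"
        elif len(alt) > len(ref):
            vtype = "insertion"
        else:
            vtype = "deletion"
        gene = rec.INFO.get("GENE") or (gene_of or {}).get(rec.CHROM, rec.CHROM)
        depth = fetch(rec, fm["depth"])
        vaf = fetch(rec, fm["vaf"])
        out.append(
            VariantCall(
                sample_id=sample_id, gene=str(gene), chrom=rec.CHROM, pos=rec.POS,
                ref=ref, alt=alt, variant_type=vtype,
                variant_class=normalize_variant_class(rec.INFO.get("CLASS", "other")),
                depth=int(depth) if depth is not None else 0,
                vaf=float(vaf) if vaf is not None else 0.0,
                origin=origin,
            )
        )
    return out
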