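"""Shared cohort container tying together sample sheet, variants and depths.

The two clinical groups are ``EEC`` (endometrioid endometrial carcinoma) and
``EIN`` (endometrial intraepithelial neoplasia, the precursor lesion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .variants import SOMATIC, VariantCall

GROUP_EEC = "EEC"
GROUP_EIN = "EIN"
GROUPS = (GROUP_EEC, GROUP_EIN)

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "grade", "stage"]


@dataclass
class Cohort:
    """A cohort bundle: sample sheet, variant records, region depths, truth.

    ``samples`` has columns sample_id/group/grade/stage; ``region_depths``
    (optional) is long-format with sample_id, chrom, start, end, gene,
    region_index, tumor_depth, normal_depth (BED convention, 0-based
    half-open). ``truth`` carries simulator ground truth and is absent for
    real data.
    """

    samples: pd.DataFrame
    somatic: list[VariantCall] = field(default_factory=list)
    germline: list[VariantCall] = field(default_factory=list)
    region_depths: Optional[pd.DataFrame] = None
    panel: Optional[dict[str, int]] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in sample sheet: {dupes}")
        bad_groups = sorted(set(self.samples["group"]) - set(GROUPS))
        if bad_groups:
            raise ValidationError(f"unknown group labels: {bad_groups}")
        known = set(ids)
        for v in self.somatic + self.germline:
            if v.sample_id not in known:
                raise ValidationError(
                    f"variant references unknown sample {v.sample_id!r} (field: sample_id)"
                )
        if self.region_depths is not None and len(self.region_depths):
            unknown = set(self.region_depths["sample_id"]) - known
            if unknown:
                raise ValidationError(
                    f"region depths reference unknown samples: {sorted(unknown)}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def groups(self) -> dict[str, str]:
        """sample_id -> group label."""
        return dict(zip(self.samples["sample_id"], self.samples["group"]))

    def group_sizes(self) -> dict[str, int]:
        return self.samples["group"].value_counts().to_dict()

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == group, "sample_id"])

    def somatic_by_sample(self) -> dict[str, list[VariantCall]]:
        out: dict[str, list[VariantCall]] = {s: [] for s in self.sample_ids}
        for v in self.somatic:
            out[v.sample_id].append(v)
        return out

    def mutated_samples(self, gene: str) -> set[str]:
        """Samples carrying >=1 somatic variant in ``gene`` (counted once)."""
        return {v.sample_id for v in self.somatic if v.gene == gene and v.origin == SOMATIC}

    def genes(self) -> list[str]:
        """Genes with at least one somatic variant, sorted."""
        return sorted({v.gene for v in self.somatic})


def somatic_frame(variants: Sequence[VariantCall]) -> pd.DataFrame:
    """Variant records as a DataFrame (one row per record, model columns)."""
    from .io import VARIANT_COLUMNS, variant_to_row

    return pd.DataFrame(
        [variant_to_row(v) for v in variants], columns=VARIANT_COLUMNS
    )
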