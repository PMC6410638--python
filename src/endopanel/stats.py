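"""Per-gene prevalence, 2x2 association tests and co-mutation analysis.

Group comparisons of mutation frequency use the classical SPSS-style
convention: continuity-corrected (Yates) Pearson chi-square when every
expected cell count is at least 5, otherwise the two-sided Fisher exact
test. The Fisher p-value is the sum of the probabilities of all tables with
the observed margins whose point probability does not exceed the observed
table's — computed here in exact integer arithmetic, so the result is the
correctly rounded float of the underlying rational number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .errors import ValidationError

PEARSON_YATES = "pearson_yates"
FISHER_EXACT = "fisher_exact"

Table = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class AssociationPolicy:
    """Test-selection rule for 2x2 tables.

    Pearson chi-square with Yates continuity correction when all expected
    counts are >= ``min_expected``; two-sided Fisher exact otherwise, and as
    an automatic fallback when a margin is zero (where the chi-square is
    undefined).
    """

    min_expected: float = 5.0


@dataclass(frozen=True)
class ContingencyResult:
    label: str
    table: Table
    test_used: str
    statistic: Optional[float]
    p_two_sided: float
    min_expected: float


def _as_table(table) -> Table:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValidationError("table entries must be non-negative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    return ((a, b), (c, d))


@lru_cache(maxsize=None)
def _comb_row(n: int) -> tuple[int, ...]:
    return tuple(math.comb(n, k) for k in range(n + 1))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    Sums the conditional probabilities (fixed margins) of every table whose
    point probability is <= the observed table's, with exact integer
    comparisons (no floating-point tie tolerance). Degenerate tables with a
    zero margin have a single attainable table and return p = 1.
    """
    ((a, b), (c, d)) = _as_table(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    row1, row2 = _comb_row(r1), _comb_row(r2)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = row1[a] * row2[c1 - a]
    num = 0
    for x in range(lo, hi + 1):
        w = row1[x] * row2[c1 - x]
        if w <= w_obs:
            num += w
    return float(Fraction(num, math.comb(n, c1)))


def yates_chi2(table) -> tuple[float, float]:
    """Continuity-corrected Pearson chi-square statistic and two-sided p."""
    ((a, b), (c, d)) = _as_table(table)
    stat, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=True)
    return float(stat), float(p)


def expected_counts(table) -> np.ndarray:
    ((a, b), (c, d)) = _as_table(table)
    arr = np.array([[a, b], [c, d]], float)
    n = arr.sum()
    if n == 0:
        return np.zeros((2, 2))
    return np.outer(arr.sum(1), arr.sum(0)) / n


def test_association(
    table, policy: AssociationPolicy = AssociationPolicy(), label: str = ""
) -> ContingencyResult:
    """Test a 2x2 group-by-mutation table under the selection policy."""
    t = _as_table(table)
    exp = expected_counts(t)
    arr = np.array(t)
    degenerate = (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any()
    min_exp = float(exp.min())
    if degenerate or min_exp < policy.min_expected:
        return ContingencyResult(
            label, t, FISHER_EXACT, None, fisher_exact_two_sided(t), min_exp
        )
    stat, p = yates_chi2(t)
    return ContingencyResult(label, t, PEARSON_YATES, stat, p, min_exp)


# -- cohort-level machinery ----------------------------------------------------


def prevalence_table(cohort: Cohort, min_mutated: int = 1) -> pd.DataFrame:
    """Per-gene mutated-sample counts, overall and per group.

    A sample counts once per gene regardless of how many variants it carries
    there. Rows are genes with overall mutated count >= ``min_mutated``,
    sorted by descending overall count, ties lexicographic. Percentage is
    100 x mutated_overall / n_overall.
    """
    sizes = cohort.group_sizes()
    n_eec = sizes.get("EEC", 0)
    n_ein = sizes.get("EIN", 0)
    n_all = n_eec + n_ein
    groups = cohort.groups
    seen: dict[str, set[str]] = {}
    for v in cohort.somatic:
        seen.setdefault(v.gene, set()).add(v.sample_id)
    rows = []
    for gene, carriers in seen.items():
        m_eec = sum(groups[s] == "EEC" for s in carriers)
        m_ein = len(carriers) - m_eec
        total = len(carriers)
        if total < min_mutated:
            continue
        rows.append(
            {
                "gene": gene,
                "mutated_overall": total,
                "n_overall": n_all,
                "percentage": 100.0 * total / n_all if n_all else 0.0,
                "mutated_eec": m_eec,
                "n_eec": n_eec,
                "mutated_ein": m_ein,
                "n_ein": n_ein,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "mutated_overall", "n_overall", "percentage",
            "mutated_eec", "n_eec", "mutated_ein", "n_ein",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["mutated_overall", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def gene_table(cohort: Cohort, gene: str) -> Table:
    """The gene's 2x2 table: rows (EEC, EIN), columns (mutated, wild-type)."""
    carriers = cohort.mutated_samples(gene)
    sizes = cohort.group_sizes()
    m_eec = sum(1 for s in carriers if cohort.groups[s] == "EEC")
    m_ein = len(carriers) - m_eec
    return (
        (m_eec, sizes.get("EEC", 0) - m_eec),
        (m_ein, sizes.get("EIN", 0) - m_ein),
    )


@dataclass(frozen=True)
class ComutationResult:
    gene_a: str
    gene_b: str
    n_co_eec: int
    n_co_ein: int
    share_eec: float
    share_ein: float
    association: ContingencyResult


def comutation(cohort: Cohort, gene_a: str, gene_b: str) -> ComutationResult:
    """Concurrent-mutation analysis for a gene pair.

    A sample is co-mutated iff it carries >=1 somatic variant in *each*
    gene. Shares are taken against group sizes; the association test
    contrasts co-mutation status between groups.
    """
    co = cohort.mutated_samples(gene_a) & cohort.mutated_samples(gene_b)
    sizes = cohort.group_sizes()
    n_eec, n_ein = sizes.get("EEC", 0), sizes.get("EIN", 0)
    co_eec = sum(1 for s in co if cohort.groups[s] == "EEC")
    co_ein = len(co) - co_eec
    table = ((co_eec, n_eec - co_eec), (co_ein, n_ein - co_ein))
    return ComutationResult(
        gene_a=gene_a,
        gene_b=gene_b,
        n_co_eec=co_eec,
        n_co_ein=co_ein,
        share_eec=co_eec / n_eec if n_eec else 0.0,
        share_ein=co_ein / n_ein if n_ein else 0.0,
        association=test_association(table, label=f"{gene_a}+{gene_b}"),
    )


@dataclass(frozen=True)
class DifferentialScreen:
    results: pd.DataFrame  # one row per screened gene
    significant: list[str]
    alpha: float
    correction: str


def differential_screen(
    cohort: Cohort,
    min_mutated: int = 1,
    alpha: float = 0.05,
    correction: str = "none",
    policy: AssociationPolicy = AssociationPolicy(),
) -> DifferentialScreen:
    """Screen every prevalence-table gene for a group frequency difference.

    Significance is judged on raw two-sided p-values by default; with
    ``correction="BH"`` the Benjamini-Hochberg adjusted values are used
    instead.
    """
    if correction not in {"none", "BH"}:
        raise ValidationError(f"correction must be 'none' or 'BH', got {correction!r}")
    prev = prevalence_table(cohort, min_mutated=min_mutated)
    rows = []
    for _, r in prev.iterrows():
        table = (
            (int(r.mutated_eec), int(r.n_eec - r.mutated_eec)),
            (int(r.mutated_ein), int(r.n_ein - r.mutated_ein)),
        )
        res = test_association(table, policy, label=r.gene)
        rows.append(
            {
                "gene": r.gene,
                "mutated_overall": int(r.mutated_overall),
                "percentage": r.percentage,
                "mutated_eec": int(r.mutated_eec),
                "n_eec": int(r.n_eec),
                "mutated_ein": int(r.mutated_ein),
                "n_ein": int(r.n_ein),
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p_two_sided": res.p_two_sided,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "mutated_overall", "percentage", "mutated_eec", "n_eec",
            "mutated_ein", "n_ein", "test_used", "statistic", "p_two_sided",
        ],
    )
    if len(df):
        if correction == "BH":
            df["p_adjusted"] = multipletests(df["p_two_sided"], method="fdr_bh")[1]
            sig_mask = df["p_adjusted"] < alpha
        else:
            df["p_adjusted"] = np.nan
            sig_mask = df["p_two_sided"] < alpha
        significant = sorted(df.loc[sig_mask, "gene"])
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
        significant = []
    return DifferentialScreen(df, significant, alpha, correction)


def crosstab(cohort: Cohort, gene: str, covariate: str) -> pd.DataFrame:
    """Counts of gene-mutated samples per level of a clinical covariate.

    ``covariate`` is one of grade, stage, group. All levels present in the
    sample sheet are retained, including those with zero mutated samples.
    """
    if covariate not in {"grade", "stage", "group"}:
        raise ValidationError(f"covariate must be grade/stage/group, got {covariate!r}")
    carriers = cohort.mutated_samples(gene)
    levels = sorted(cohort.samples[covariate].astype(str).unique())
    by_level = dict.fromkeys(levels, 0)
    lookup = dict(zip(cohort.samples["sample_id"], cohort.samples[covariate].astype(str)))
    for s in carriers:
        by_level[lookup[s]] += 1
    return pd.DataFrame(
        {"level": levels, "mutated_samples": [by_level[l] for l in levels]}
    )


_CLASS_CODES = {
    "missense": "M",
    "nonsense": "N",
    "frameshift": "F",
    "nonframeshift_indel": "I",
    "splice": "S",
    "synonymous": "Y",
    "other": "O",
}
# priority when a sample has several classes in one gene: truncating first
_CLASS_PRIORITY = ["nonsense", "frameshift", "splice", "missense",
                   "nonframeshift_indel", "synonymous", "other"]


def oncoprint_matrix(cohort: Cohort) -> pd.DataFrame:
    """Genes x samples matrix of variant-class codes ('.' = wild-type).

    When a sample carries several variant classes in one gene the
    highest-priority (most disruptive) class is shown.
    """
    cells: dict[str, dict[str, set[str]]] = {}
    for v in cohort.somatic:
        cells.setdefault(v.gene, {}).setdefault(v.sample_id, set()).add(v.variant_class)
    genes = sorted(cells)
    mat = pd.DataFrame(".", index=genes, columns=cohort.sample_ids)
    for gene, per_sample in cells.items():
        for s, classes in per_sample.items():
            best = min(classes, key=_CLASS_PRIORITY.index)
            mat.loc[gene, s] = _CLASS_CODES[best]
    mat.index.name = "gene"
    return mat
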