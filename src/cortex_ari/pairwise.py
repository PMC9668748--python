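"""Paired regional differential expression: the primitive of every ARI statistic.

For one unordered pair of cortical regions and one diagnosis group, subjects
possessing both regions contribute one within-subject paired difference per
gene (posterior-ranked region minus anterior-ranked region). Genes are tested
with the paired Wilcoxon signed-rank test and counted as differentially
expressed at BH FDR q < alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import REGIONS_AP, region_ranks
from .stats import bh_adjust, signed_rank_pvalues

CONTROL_LABEL = "control"


class InfeasiblePairError(ValueError):
    """Raised when a regional comparison has too few paired subjects."""


@dataclass(frozen=True)
class PairKey:
    """Unordered pair of distinct regions stored in canonical rank order."""

    region_a: str
    region_b: str

    def __post_init__(self) -> None:
        if self.region_a == self.region_b:
            raise ValueError("a region pair needs two distinct regions")

    @classmethod
    def make(cls, a: str, b: str, regions: tuple[str, ...] | list[str] = REGIONS_AP) -> "PairKey":
        """Build a pair in canonical order (anterior region first).

        Regions absent from the configured ordering sort after configured
        ones, alphabetically, so the canonical order is always stable.
        """
        ranks = region_ranks(tuple(regions))
        key = lambda r: (ranks.get(r, len(ranks) + 1), r)
        a, b = sorted((a, b), key=key)
        return cls(a, b)

    def __str__(self) -> str:
        return f"{self.region_a}|{self.region_b}"


def all_region_pairs(regions: tuple[str, ...] | list[str] = REGIONS_AP) -> list[PairKey]:
    """All unique unordered region pairs in canonical order (55 for 11 regions)."""
    return [PairKey.make(a, b, regions) for a, b in itertools.combinations(regions, 2)]


def is_case(diagnosis: pd.Series) -> pd.Series:
    """Case/control dichotomy: any non-control label (ASD, dup15q, ...) is a case."""
    return diagnosis.astype(str) != CONTROL_LABEL


def group_mask(meta: pd.DataFrame, group: str) -> pd.Series:
    if group not in ("control", "case"):
        raise ValueError(f"group must be 'control' or 'case', got {group!r}")
    case = is_case(meta["diagnosis"])
    return case if group == "case" else ~case


def paired_subjects(meta: pd.DataFrame, pair: PairKey, group: str) -> list[str]:
    """Subjects of the group possessing both regions of the pair, sorted by id."""
    sub = meta[group_mask(meta, group)]
    with_a = set(sub.loc[sub["region"] == pair.region_a, "subject_id"])
    with_b = set(sub.loc[sub["region"] == pair.region_b, "subject_id"])
    return sorted(with_a & with_b)


def paired_differences(
    expr: pd.DataFrame, meta: pd.DataFrame, pair: PairKey, subjects: list[str]
) -> np.ndarray:
    """(n_genes, n_subjects) matrix of expr(region_b) - expr(region_a).

    Assumes at most one sample per (subject, region), the post-QC invariant.
    """
    idx = meta.set_index(["subject_id", "region"])["sample_id"]
    cols_a = [idx[(s, pair.region_a)] for s in subjects]
    cols_b = [idx[(s, pair.region_b)] for s in subjects]
    return expr[cols_b].to_numpy() - expr[cols_a].to_numpy()


@dataclass
class DEResult:
    """Per-gene paired signed-rank outcomes for one (pair, group) comparison."""

    pair: PairKey
    group: str
    n_subjects: int
    alpha: float
    table: pd.DataFrame | None  # gene_id index: p, q, direction, de_flag, median_diff, mean_diff
    n_de: int | None
    feasible: bool = True
    de_genes: frozenset = field(default_factory=frozenset)


def count_de(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pair: PairKey,
    group: str,
    alpha: float = 0.05,
) -> DEResult:
    """Count differentially expressed genes between two regions within a group.

    Per gene the within-subject difference expr(region_b) - expr(region_a) is
    tested with the paired Wilcoxon signed-rank test across subjects having
    both regions; BH adjustment is applied across all genes of the matrix and
    genes with q < alpha are counted as DE. With fewer than two paired
    subjects the result is returned flagged infeasible (n_de None).
    """
    subjects = paired_subjects(meta, pair, group)
    if len(subjects) < 2:
        return DEResult(pair, group, len(subjects), alpha, None, None, feasible=False)
    D = paired_differences(expr, meta, pair, subjects)
    p = signed_rank_pvalues(D)
    q = bh_adjust(p)
    med = np.median(D, axis=1)
    direction = np.sign(med).astype(int)
    de_flag = q < alpha
    table = pd.DataFrame(
        {
            "p": p,
            "q": q,
            "direction": direction,
            "de_flag": de_flag,
            "median_diff": med,
            "mean_diff": D.mean(axis=1),
        },
        index=pd.Index(expr.index, name="gene_id"),
    )
    return DEResult(
        pair=pair,
        group=group,
        n_subjects=len(subjects),
        alpha=alpha,
        table=table,
        n_de=int(de_flag.sum()),
        de_genes=frozenset(table.index[de_flag]),
    )
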