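"""ARI gene extraction: occurrence filtering, region assignment, grouping.

From each region pair classified attenuated by the permutation test, genes
that are DE in the true control subjects are filtered by how often they were
DE in the pseudo-control groups of the permutations: genes DE in at least
95% of permutations are labelling-insensitive (their regional difference
survives diagnosis mixing, so it carries no attenuation signal) and are
dropped. Retained genes are assigned to the region where control expression
is higher, then pooled (union without duplicates) across attenuated pairs
and split by the sign of the association between control regional expression
and the anterior-posterior axis: genes increasing posteriorly in controls
form the ARI-downregulated group, genes decreasing posteriorly the
ARI-upregulated group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pairwise import DEResult, PairKey, group_mask
from .permutation import ari_test

log = logging.getLogger(__name__)


@dataclass
class ARIGeneRecord:
    """One retained ARI gene from one attenuated regional comparison."""

    gene_id: str
    pair: PairKey
    occurrence_fraction: float
    assigned_region: str
    control_pair_p: float
    group: str | None = None  # "ari_down" | "ari_up", set by build_ari_groups


@dataclass
class ARIGroups:
    """Union ARI gene sets along the anterior-posterior axis."""

    ari_down: frozenset  # higher posterior expression in controls, attenuated in cases
    ari_up: frozenset    # lower posterior expression in controls, attenuated in cases
    unassigned: frozenset = field(default_factory=frozenset)


def permutation_occurrence(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pair: PairKey,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Per-gene count of permutations in which the gene was pseudo-control DE.

    Replays the identical permutation stream as :func:`ari_test` with the
    same seed, so occurrences refer literally to the permutations of the
    attenuation test.
    """
    outcome = ari_test(
        expr, meta, pair, B=B, alpha=alpha, seed=seed, track_occurrence=True
    )
    return outcome.occurrence


def filter_ari_genes(
    true_control_de: DEResult,
    occurrence: pd.Series | dict,
    B: int,
    threshold: float = 0.95,
) -> list[ARIGeneRecord]:
    """Occurrence-filter the true-control DE genes of one attenuated pair.

    A gene is retained iff occurrence/B < ``threshold`` (strict). The
    assigned region is the pair member with the larger control median
    expression across paired subjects (sign of the median within-subject
    difference); exact zero medians fall back to the mean difference, and a
    gene with both zero is excluded with a warning.
    """
    if true_control_de.table is None:
        raise ValueError("true control DE result is infeasible")
    occ = pd.Series(occurrence, dtype=float)
    pair = true_control_de.pair
    records: list[ARIGeneRecord] = []
    de = true_control_de.table[true_control_de.table["de_flag"]]
    missing = de.index.difference(occ.index)
    if len(missing):
        raise ValueError(f"occurrence undefined for DE genes: {list(missing)[:5]} ...")
    for gene, row in de.iterrows():
        frac = float(occ[gene]) / B
        if not frac < threshold:
            continue
        sign = row["median_diff"]
        if sign == 0:
            sign = row["mean_diff"]
        if sign == 0:
            log.warning("gene %s: no expression difference direction; excluded", gene)
            continue
        # paired difference is region_b - region_a
        assigned = pair.region_b if sign > 0 else pair.region_a
        records.append(
            ARIGeneRecord(
                gene_id=str(gene),
                pair=pair,
                occurrence_fraction=frac,
                assigned_region=assigned,
                control_pair_p=float(row["p"]),
            )
        )
    return records


def control_region_medians(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Median control expression per gene per region (genes x regions)."""
    ctrl = meta[~group_mask(meta, "case")]
    cols = {}
    for region, g in ctrl.groupby("region"):
        cols[region] = expr[list(g["sample_id"])].median(axis=1)
    return pd.DataFrame(cols)


def build_ari_groups(
    records_by_pair: dict[PairKey, list[ARIGeneRecord]] | list[list[ARIGeneRecord]],
    region_ranks: dict[str, int],
    control_summary: pd.DataFrame,
) -> ARIGroups:
    """Union the per-pair retained genes and split along the A-P axis.

    Each gene (once, regardless of how many source pairs retained it) is
    grouped by the sign of the Spearman correlation between its control
    median expression across regions and the anterior-posterior rank:
    positive (expression rises posteriorly) -> ari_down, negative -> ari_up,
    zero -> unassigned (logged). A gene retained with contradictory
    per-pair directions is resolved by this all-region correlation.
    """
    lists = (
        list(records_by_pair.values())
        if isinstance(records_by_pair, dict)
        else records_by_pair
    )
    all_records = [r for recs in lists for r in recs]
    if not all_records:
        raise ValueError("no retained ARI gene records")
    genes = sorted({r.gene_id for r in all_records})

    regions = [r for r in control_summary.columns if r in region_ranks]
    ranks = np.array([region_ranks[r] for r in regions], dtype=float)
    down, up, unassigned = set(), set(), set()
    import warnings as _warnings

    for gene in genes:
        prof = control_summary.loc[gene, regions].to_numpy(dtype=float)
        with _warnings.catch_warnings():
            # a flat profile yields an undefined correlation, handled below
            _warnings.simplefilter("ignore", sps.ConstantInputWarning)
            rho = sps.spearmanr(prof, ranks).statistic
        if np.isnan(rho) or rho == 0:
            log.warning("gene %s: no monotone A-P trend; left unassigned", gene)
            unassigned.add(gene)
        elif rho > 0:
            down.add(gene)
        else:
            up.add(gene)
    for recs in lists:
        for r in recs:
            r.group = (
                "ari_down" if r.gene_id in down
                else "ari_up" if r.gene_id in up
                else None
            )
    return ARIGroups(frozenset(down), frozenset(up), frozenset(unassigned))


def records_table(records: list[ARIGeneRecord]) -> pd.DataFrame:
    """Flat table of ARI gene records."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "source_pair": [str(r.pair) for r in records],
            "occurrence_fraction": [r.occurrence_fraction for r in records],
            "assigned_region": [r.assigned_region for r in records],
            "control_pair_p": [r.control_pair_p for r in records],
            "group": [r.group for r in records],
        }
    )
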