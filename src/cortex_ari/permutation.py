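"""Permutation test for attenuation of regional identity at one region pair.

The statistic is the difference in DE gene counts, n_de(case) - n_de(control),
for a pair of regions. The null is built by randomly reassigning diagnosis
labels across the subjects that possess both regions, preserving group sizes,
and recomputing both counts under the identical signed-rank and BH rules.
A two-tailed p-value compares |true difference| against the permuted
|differences| with the add-one estimator; a pair is classified attenuated
when the test is significant and cases show fewer DE genes than controls,
over-patterned when significant in the opposite direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairwise import (
    DEResult,
    InfeasiblePairError,
    PairKey,
    count_de,
    paired_differences,
    paired_subjects,
)
from .stats import bh_reject_count, bh_reject_mask, signed_rank_pvalues

ATTENUATED = "attenuated"
OVER_PATTERNED = "over_patterned"
NOT_SIGNIFICANT = "not_significant"


@dataclass
class PermutationOutcome:
    """Result of the label-permutation attenuation test for one region pair."""

    pair: PairKey
    n_de_control: int
    n_de_case: int
    true_diff: int
    perm_diffs: np.ndarray
    p_two_tailed: float
    classification: str
    B: int
    seed: int | None
    alpha: float
    control_de: DEResult | None = None
    case_de: DEResult | None = None
    occurrence: pd.Series | None = None  # per-gene pseudo-control DE counts


def permute_labels(
    subjects_case: list[str],
    subjects_control: list[str],
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Uniformly random relabeling preserving group sizes.

    Returns (pseudo_case, pseudo_control) partitioning the union of the two
    disjoint input lists.
    """
    if set(subjects_case) & set(subjects_control):
        raise ValueError("case and control subject lists overlap")
    if not subjects_case or not subjects_control:
        raise ValueError("both groups must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(set(subjects_case) | set(subjects_control))
    perm = rng.permutation(len(pool))
    n_case = len(subjects_case)
    return (
        [pool[i] for i in perm[:n_case]],
        [pool[i] for i in perm[n_case:]],
    )


def _classify(p: float, n_de_case: int, n_de_control: int, p_threshold: float) -> str:
    if p < p_threshold and n_de_case < n_de_control:
        return ATTENUATED
    if p < p_threshold and n_de_case > n_de_control:
        return OVER_PATTERNED
    return NOT_SIGNIFICANT


def ari_test(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pair: PairKey,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    p_threshold: float = 0.05,
    exhaustive: bool = False,
    use_cache: bool = True,
    track_occurrence: bool = False,
) -> PermutationOutcome:
    """Permutation attenuation test for one region pair.

    Parameters
    ----------
    B:
        Number of label permutations (ignored when ``exhaustive``).
    exhaustive:
        Enumerate every equal-size label assignment instead of sampling;
        the p-value is then the exact fraction of assignments whose
        |difference| reaches the true one (the true assignment is included).
    use_cache:
        Reuse the per-gene paired-difference matrix across permutations
        (the subject pairing never changes, so this is exact); disable to
        recompute from the expression matrix each time, for verification.
    track_occurrence:
        Also accumulate, per gene, the number of permutations in which the
        gene was DE in the pseudo-control group (the occurrence filter input).
        Tracking consumes no extra randomness, so outcomes with and without
        it share the identical permutation stream for a given seed.
    """
    subs_case = paired_subjects(meta, pair, "case")
    subs_ctrl = paired_subjects(meta, pair, "control")
    if len(subs_case) < 2 or len(subs_ctrl) < 2:
        raise InfeasiblePairError(
            f"pair {pair}: {len(subs_case)} case / {len(subs_ctrl)} control paired subjects"
        )
    control_de = count_de(expr, meta, pair, "control", alpha)
    case_de = count_de(expr, meta, pair, "case", alpha)
    true_diff = case_de.n_de - control_de.n_de

    pool = sorted(set(subs_case) | set(subs_ctrl))
    n_all, n_case = len(pool), len(subs_case)
    D = paired_differences(expr, meta, pair, pool) if use_cache else None

    occ = np.zeros(expr.shape[0]) if track_occurrence else None

    def counts_for(idx_case: np.ndarray, idx_ctrl: np.ndarray) -> tuple[int, int]:
        if use_cache:
            p_case = signed_rank_pvalues(D[:, idx_case])
            p_ctrl = signed_rank_pvalues(D[:, idx_ctrl])
        else:
            Dc = paired_differences(expr, meta, pair, [pool[i] for i in idx_case])
            Dk = paired_differences(expr, meta, pair, [pool[i] for i in idx_ctrl])
            p_case = signed_rank_pvalues(Dc)
            p_ctrl = signed_rank_pvalues(Dk)
        if occ is not None:
            occ[bh_reject_mask(p_ctrl, alpha)] += 1
        return bh_reject_count(p_case, alpha), bh_reject_count(p_ctrl, alpha)

    if exhaustive:
        diffs = []
        for combo in itertools.combinations(range(n_all), n_case):
            idx_case = np.array(combo)
            idx_ctrl = np.array([i for i in range(n_all) if i not in set(combo)])
            nc, nk = counts_for(idx_case, idx_ctrl)
            diffs.append(nc - nk)
        perm_diffs = np.array(diffs)
        p = float(np.mean(np.abs(perm_diffs) >= abs(true_diff)))
        B_eff, used_seed = len(diffs), None
    else:
        rng = np.random.default_rng(seed)
        perm_diffs = np.empty(B, dtype=int)
        for b in range(B):
            order = rng.permutation(n_all)
            nc, nk = counts_for(order[:n_case], order[n_case:])
            perm_diffs[b] = nc - nk
        p = float((1 + np.sum(np.abs(perm_diffs) >= abs(true_diff))) / (B + 1))
        B_eff, used_seed = B, seed

    return PermutationOutcome(
        pair=pair,
        n_de_control=control_de.n_de,
        n_de_case=case_de.n_de,
        true_diff=int(true_diff),
        perm_diffs=perm_diffs,
        p_two_tailed=p,
        classification=_classify(p, case_de.n_de, control_de.n_de, p_threshold),
        B=B_eff,
        seed=used_seed,
        alpha=alpha,
        control_de=control_de,
        case_de=case_de,
        occurrence=(
            pd.Series(occ, index=expr.index, name="occurrence")
            if occ is not None
            else None
        ),
    )


def outcomes_table(outcomes: list[PermutationOutcome]) -> pd.DataFrame:
    """Summary table of permutation outcomes, one row per region pair."""
    return pd.DataFrame(
        {
            "pair": [str(o.pair) for o in outcomes],
            "n_de_control": [o.n_de_control for o in outcomes],
            "n_de_case": [o.n_de_case for o in outcomes],
            "true_diff": [o.true_diff for o in outcomes],
            "p": [o.p_two_tailed for o in outcomes],
            "classification": [o.classification for o in outcomes],
            "B": [o.B for o in outcomes],
        }
    )
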