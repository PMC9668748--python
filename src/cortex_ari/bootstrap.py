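"""Bootstrap attenuation test with age-matched subject subsetting.

The permutation test is sensitive to per-pair subject counts, so DE counts
are not comparable across region pairs. The bootstrap route equalises the
design: each pair is subset to k (default 10) case and k control subjects
closest in age to the group median, subjects are resampled with replacement
B times, the DE count recomputed per draw, and the resulting control and
case count distributions compared with a two-sample Mann-Whitney rank test,
BH-corrected across the pairs tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from zlib import crc32

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pairwise import InfeasiblePairError, PairKey, paired_differences, paired_subjects
from .stats import bh_adjust, bh_reject_count, signed_rank_pvalues


@dataclass
class BootstrapOutcome:
    """Bootstrap DE-count distributions and attenuation call for one pair."""

    pair: PairKey
    subset_size: int
    control_counts: np.ndarray
    case_counts: np.ndarray
    mw_p: float
    q: float | None
    attenuated: bool | None
    seed: int


def pair_seed(master_seed: int, pair: PairKey) -> list[int]:
    """Deterministic per-pair seed material; adding pairs never shifts streams."""
    return [int(master_seed), crc32(str(pair).encode())]


def age_matched_subset(
    subject_ids: list[str], ages: list[float] | np.ndarray, k: int = 10
) -> list[str]:
    """The k subjects closest in age to the median age of those available.

    Ties in |age - median| are broken by sorted subject id; the result is
    deterministic and returned sorted by subject id.
    """
    if len(subject_ids) != len(ages):
        raise ValueError("subject_ids and ages must align")
    if len(subject_ids) < k:
        raise InfeasiblePairError(
            f"{len(subject_ids)} subjects available but {k} required"
        )
    med = float(np.median(np.asarray(ages, dtype=float)))
    order = sorted(
        range(len(subject_ids)),
        key=lambda i: (abs(float(ages[i]) - med), subject_ids[i]),
    )
    return sorted(subject_ids[i] for i in order[:k])


def subject_ages(meta: pd.DataFrame, subjects: list[str]) -> np.ndarray:
    """Subject-level ages (first metadata occurrence per subject)."""
    ages = meta.drop_duplicates("subject_id").set_index("subject_id")["age"]
    return ages.loc[subjects].to_numpy(dtype=float)


def bootstrap_counts(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pair: PairKey,
    group_subjects: list[str],
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int | list[int] | np.random.Generator = 0,
) -> np.ndarray:
    """DE counts over B resamples of the subject subset with replacement.

    A subject drawn twice contributes its paired difference twice, creating
    exact ties that the signed-rank null handles by enumeration.
    """
    D = paired_differences(expr, meta, pair, sorted(group_subjects))
    k = D.shape[1]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = np.empty(B, dtype=int)
    for b in range(B):
        cols = rng.integers(0, k, size=k)
        counts[b] = bh_reject_count(signed_rank_pvalues(D[:, cols]), alpha)
    return counts


def bootstrap_ari(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: list[PairKey],
    B: int = 10_000,
    k: int = 10,
    alpha: float = 0.05,
    fdr: float = 0.05,
    seed: int = 0,
) -> list[BootstrapOutcome]:
    """Bootstrap attenuation test across region pairs.

    Per pair: age-match both groups to k subjects, bootstrap the DE count in
    each group, compare the two count distributions with a two-sided
    Mann-Whitney U test (p = 1 if all counts are identical in both groups),
    then BH-adjust across the tested pairs; a pair is attenuated iff
    q < ``fdr`` and the median case count is below the median control count.
    Per-pair random streams are derived independently from the master seed.
    """
    outcomes: list[BootstrapOutcome] = []
    for pair in pairs:
        subs = {g: paired_subjects(meta, pair, g) for g in ("control", "case")}
        chosen = {}
        for g, s in subs.items():
            if len(s) < k:
                raise InfeasiblePairError(
                    f"pair {pair}: only {len(s)} paired {g} subjects (< {k})"
                )
            chosen[g] = age_matched_subset(s, subject_ages(meta, s), k)
        ss = np.random.SeedSequence(pair_seed(seed, pair))
        rng_ctrl, rng_case = [np.random.default_rng(c) for c in ss.spawn(2)]
        counts_ctrl = bootstrap_counts(expr, meta, pair, chosen["control"], B, alpha, rng_ctrl)
        counts_case = bootstrap_counts(expr, meta, pair, chosen["case"], B, alpha, rng_case)
        pooled = np.concatenate([counts_ctrl, counts_case])
        if np.all(pooled == pooled[0]):
            mw_p = 1.0
        else:
            mw_p = float(
                sps.mannwhitneyu(counts_ctrl, counts_case, alternative="two-sided").pvalue
            )
        outcomes.append(
            BootstrapOutcome(
                pair=pair,
                subset_size=k,
                control_counts=counts_ctrl,
                case_counts=counts_case,
                mw_p=mw_p,
                q=None,
                attenuated=None,
                seed=seed,
            )
        )
    qs = bh_adjust(np.array([o.mw_p for o in outcomes]))
    for o, q in zip(outcomes, qs):
        o.q = float(q)
        o.attenuated = bool(
            q < fdr and np.median(o.case_counts) < np.median(o.control_counts)
        )
    return outcomes


def bootstrap_table(outcomes: list[BootstrapOutcome]) -> pd.DataFrame:
    """Summary table of bootstrap outcomes, one row per region pair."""
    return pd.DataFrame(
        {
            "pair": [str(o.pair) for o in outcomes],
            "median_control": [float(np.median(o.control_counts)) for o in outcomes],
            "median_case": [float(np.median(o.case_counts)) for o in outcomes],
            "mw_p": [o.mw_p for o in outcomes],
            "q": [o.q for o in outcomes],
            "attenuated": [o.attenuated for o in outcomes],
        }
    )
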