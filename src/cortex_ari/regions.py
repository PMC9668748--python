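"""Cortical region labels, anterior-posterior ordering, and lobe assignment.

The default region set is the 11 Brodmann-area groupings profiled in
multi-region cortical transcriptomic studies, ordered roughly along the
anterior-posterior axis (rank 1 = most anterior, rank 11 = most posterior,
BA17/primary visual cortex). The ordering is a modelling convention used by
the synthetic generator and the ARI gene grouping; any ordered list of
unique labels may be substituted.
"""

from __future__ import annotations

REGIONS_AP: tuple[str, ...] = (
    "BA9",
    "BA44/45",
    "BA24",
    "BA4/6",
    "BA38",
    "BA3/1/2/5",
    "BA41/42/22",
    "BA20/37",
    "BA7",
    "BA39/40",
    "BA17",
)

# Cortical lobe of each default region; used to group samples for outlier QC.
REGION_LOBE: dict[str, str] = {
    "BA9": "frontal",
    "BA44/45": "frontal",
    "BA24": "frontal",
    "BA4/6": "frontal",
    "BA38": "temporal",
    "BA41/42/22": "temporal",
    "BA20/37": "temporal",
    "BA3/1/2/5": "parietal",
    "BA7": "parietal",
    "BA39/40": "parietal",
    "BA17": "occipital",
}


def region_ranks(regions: tuple[str, ...] | list[str] = REGIONS_AP) -> dict[str, int]:
    """Map each region label to its 1-based anterior-posterior rank."""
    if len(set(regions)) != len(regions):
        raise ValueError("region labels must be unique")
    return {r: i + 1 for i, r in enumerate(regions)}


def sanitize_region(label: str) -> str:
    """Region label made filesystem/sample-id safe ('BA44/45' -> 'BA44-45')."""
    return label.replace("/", "-")
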