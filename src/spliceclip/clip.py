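"""Replicate-consensus recipes for CLIP binding-site interval files.

Three dataset-specific recipes reduce replicated interval files to one
consensus set:

* PAR-CLIP clusters: read-count filter, then cross-replicate intersection.
* HITS-CLIP crosslink sites: within-replicate merge, then intersection.
* FLASH-CLIP crosslink sites: within-replicate merge summing PCR-duplicate
  scores, score filter, then intersection.

"Intersect across biological repeats" is applied strictly: an interval is
kept only if it overlaps a retained interval in *every* other replicate.
Intersection is strand-aware when the inputs carry concrete strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import (
    GenomicInterval,
    IntervalError,
    IntervalIndex,
    merge,
    merge_scored,
)

__all__ = [
    "ClipReplicate",
    "consensus_parclip",
    "consensus_hitsclip",
    "consensus_flashclip",
]


@dataclass(frozen=True)
class ClipReplicate:
    """One biological replicate's called binding sites / crosslink clusters."""

    replicate_id: str
    sites: tuple[GenomicInterval, ...]

    def __init__(self, replicate_id: str, sites: Sequence[GenomicInterval]):
        object.__setattr__(self, "replicate_id", replicate_id)
        object.__setattr__(self, "sites", tuple(sites))


def _stranded(replicate_sets: Sequence[Sequence[GenomicInterval]]) -> bool:
    sites = [iv for sites in replicate_sets for iv in sites]
    return bool(sites) and all(iv.strand != "." for iv in sites)


def _cross_replicate(
    replicate_sets: Sequence[list[GenomicInterval]], strand_aware: bool
) -> list[GenomicInterval]:
    """Keep intervals overlapping >= 1 interval in every other replicate; merge the union."""
    indexes = [IntervalIndex(merge(s, strand_aware=strand_aware) if s else []) for s in replicate_sets]
    kept: list[GenomicInterval] = []
    for i, sites in enumerate(replicate_sets):
        others = [idx for j, idx in enumerate(indexes) if j != i]
        for iv in sites:
            if all(idx.overlaps(iv, strand_aware=strand_aware) for idx in others):
                kept.append(iv)
    if not kept:
        return []
    return merge(kept, strand_aware=strand_aware)


def _check_replicates(replicates: Sequence[ClipReplicate]) -> None:
    if len(replicates) < 2:
        raise IntervalError(
            f"consensus requires >= 2 replicates, got {len(replicates)}"
        )


def consensus_parclip(
    replicates: Sequence[ClipReplicate], min_read_count: float = 40
) -> list[GenomicInterval]:
    """PAR-CLIP recipe: drop clusters with read count below ``min_read_count``
    (default 40, kept at exactly 40), then require cross-replicate overlap,
    then merge."""
    _check_replicates(replicates)
    filtered = [
        [iv for iv in rep.sites if iv.score is not None and iv.score >= min_read_count]
        for rep in replicates
    ]
    return _cross_replicate(filtered, strand_aware=_stranded(filtered))


def consensus_hitsclip(replicates: Sequence[ClipReplicate]) -> list[GenomicInterval]:
    """HITS-CLIP recipe: merge within each replicate, require cross-replicate
    overlap of the merged intervals, then merge again."""
    _check_replicates(replicates)
    raw = [list(rep.sites) for rep in replicates]
    strand_aware = _stranded(raw)
    merged = [merge(sites, strand_aware=strand_aware) if sites else [] for sites in raw]
    return _cross_replicate(merged, strand_aware=strand_aware)


def consensus_flashclip(
    replicates: Sequence[ClipReplicate], min_score: float = 10
) -> list[GenomicInterval]:
    """FLASH-CLIP recipe: merge within each replicate summing PCR-duplicate
    scores, keep merged sites with summed score >= ``min_score`` (default 10),
    require cross-replicate overlap, then merge."""
    _check_replicates(replicates)
    raw = [list(rep.sites) for rep in replicates]
    strand_aware = _stranded(raw)
    filtered: list[list[GenomicInterval]] = []
    for sites in raw:
        merged = merge_scored(sites, strand_aware=strand_aware) if sites else []
        filtered.append([iv for iv in merged if iv.score >= min_score])
    return _cross_replicate(filtered, strand_aware=strand_aware)
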