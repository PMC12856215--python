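"""Interval algebra on 0-based half-open genomic coordinates.

All coordinates follow the BED convention: ``start`` is inclusive,
``end`` is exclusive, so an interval covers ``end - start`` bases.
Strand is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "FeatureSpace",
    "IntervalError",
    "merge",
    "merge_scored",
    "subtract",
    "overlaps_any",
    "expand",
    "build_feature_space",
    "promoter_targets",
]

STRANDS = ("+", "-", ".")


class IntervalError(ValueError):
    """Raised for invalid intervals or coordinate operations."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval with optional score and name.

    ``score`` carries read counts (PAR-CLIP clusters) or PCR-duplicate
    counts (FLASH-CLIP crosslink sites) where a recipe filters on it.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                + (f" ({self.name})" if self.name else "")
                + ": require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}; expected one of {STRANDS}")
        if self.score is not None and self.score < 0:
            raise IntervalError(f"negative score {self.score} on {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", strand_aware: bool = False) -> bool:
        """True iff the two intervals share >= 1 base (and strands are compatible)."""
        if self.chrom != other.chrom:
            return False
        if strand_aware and not strands_compatible(self.strand, other.strand):
            return False
        return self.start < other.end and other.start < self.end


def strands_compatible(a: str, b: str) -> bool:
    """Unstranded ('.') matches either strand; concrete strands must be equal."""
    return a == "." or b == "." or a == b


def _group_key(iv: GenomicInterval, strand_aware: bool) -> tuple:
    return (iv.chrom, iv.strand) if strand_aware else (iv.chrom,)


def merge(
    intervals: Iterable[GenomicInterval], strand_aware: bool = False
) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals into a sorted disjoint set.

    With ``strand_aware`` every interval must carry a concrete strand and
    merging happens per (chrom, strand). Scores and names are dropped.
    """
    ivs = list(intervals)
    if strand_aware:
        for iv in ivs:
            if iv.strand == ".":
                raise IntervalError(
                    f"strand-aware merge requires concrete strands; got {iv.chrom}:{iv.start}-{iv.end} '.'"
                )
    out: list[GenomicInterval] = []
    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in ivs:
        groups.setdefault(_group_key(iv, strand_aware), []).append(iv)
    for key in sorted(groups):
        grp = sorted(groups[key], key=lambda iv: (iv.start, iv.end))
        strand = grp[0].strand if strand_aware else "."
        cur_start, cur_end = grp[0].start, grp[0].end
        for iv in grp[1:]:
            if iv.start <= cur_end:  # book-ended (==) merges too
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(key[0], cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(key[0], cur_start, cur_end, strand))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))


def merge_scored(
    intervals: Iterable[GenomicInterval], strand_aware: bool = False
) -> list[GenomicInterval]:
    """Like :func:`merge` but each merged interval's score is the sum of its members'.

    A missing score raises, since summation would silently be wrong.
    """
    ivs = list(intervals)
    for iv in ivs:
        if iv.score is None:
            raise IntervalError(
                f"merge_scored requires a score on every interval; missing on "
                f"{iv.chrom}:{iv.start}-{iv.end}"
            )
    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in ivs:
        groups.setdefault(_group_key(iv, strand_aware), []).append(iv)
    out: list[GenomicInterval] = []
    for key in sorted(groups):
        grp = sorted(groups[key], key=lambda iv: (iv.start, iv.end))
        strand = grp[0].strand if strand_aware else "."
        cur_start, cur_end, cur_score = grp[0].start, grp[0].end, grp[0].score
        for iv in grp[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
                cur_score += iv.score
            else:
                out.append(GenomicInterval(key[0], cur_start, cur_end, strand, score=cur_score))
                cur_start, cur_end, cur_score = iv.start, iv.end, iv.score
        out.append(GenomicInterval(key[0], cur_start, cur_end, strand, score=cur_score))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))


def subtract(
    minuend: Sequence[GenomicInterval], subtrahend: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``minuend`` not covered by ``subtrahend`` (strand-agnostic, per chrom).

    Both inputs should already be merged; output preserves each minuend
    interval's strand.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subtrahend:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for lst in by_chrom.values():
        lst.sort(key=lambda iv: iv.start)
    out: list[GenomicInterval] = []
    for iv in minuend:
        cuts = by_chrom.get(iv.chrom, [])
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos or cut.start >= iv.end:
                continue
            if cut.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, cut.start, iv.strand))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end, iv.strand))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))


class IntervalIndex:
    """Sorted-array index over a merged (disjoint) interval set for O(log n) overlap queries."""

    def __init__(self, merged: Sequence[GenomicInterval]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        grouped: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv in merged:
            grouped.setdefault((iv.chrom, iv.strand), []).append(iv)
        for key, ivs in grouped.items():
            ivs.sort(key=lambda iv: iv.start)
            self._by_key[key] = ([iv.start for iv in ivs], [iv.end for iv in ivs])

    def _hits_key(self, key: tuple[str, str], start: int, end: int) -> bool:
        entry = self._by_key.get(key)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start

    def overlaps(self, query: GenomicInterval, strand_aware: bool = False) -> bool:
        chrom, start, end = query.chrom, query.start, query.end
        if not strand_aware:
            return any(
                self._hits_key((chrom, s), start, end) for s in STRANDS
            )
        if query.strand == ".":
            candidates = STRANDS
        else:
            candidates = (query.strand, ".")
        return any(self._hits_key((chrom, s), start, end) for s in candidates)


def overlaps_any(
    query: GenomicInterval,
    subjects: Sequence[GenomicInterval] | IntervalIndex,
    strand_aware: bool = False,
) -> bool:
    """True iff ``query`` shares >= 1 base with any subject interval.

    ``subjects`` should be a merged/sorted set (or a prebuilt
    :class:`IntervalIndex` when querying repeatedly).
    """
    if not isinstance(subjects, IntervalIndex):
        subjects = IntervalIndex(subjects)
    return subjects.overlaps(query, strand_aware=strand_aware)


def expand(
    interval: GenomicInterval, sizes: Mapping[str, int], flank: int
) -> GenomicInterval:
    """Widen an interval by ``flank`` bp on each side, clipped to the chromosome."""
    if flank < 0:
        raise IntervalError(f"flank must be >= 0, got {flank}")
    if interval.chrom not in sizes:
        raise IntervalError(f"unknown chromosome {interval.chrom!r} in chrom sizes")
    length = sizes[interval.chrom]
    return replace(
        interval,
        start=max(0, interval.start - flank),
        end=min(length, interval.end + flank),
    )


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of disjoint exons on one chromosome/strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise IntervalError(f"gene {self.gene_id}: at least one exon required")
        if self.strand not in ("+", "-"):
            raise IntervalError(f"gene {self.gene_id}: strand must be '+' or '-'")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise IntervalError(f"gene {self.gene_id}: exon on wrong chromosome {ex.chrom}")
            if ex.start < prev_end:
                raise IntervalError(f"gene {self.gene_id}: exons must be sorted and disjoint")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcript start: first exon start on '+', last exon end - 1 on '-'."""
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class FeatureSpace:
    """Merged exonic and intronic interval sets keyed by (chrom, strand).

    Exon takes precedence over intron where genes overlap, so the two
    sets are disjoint within each (chrom, strand) — the placement domain
    for the constrained shuffle.
    """

    exonic: dict[tuple[str, str], tuple[GenomicInterval, ...]] = field(default_factory=dict)
    intronic: dict[tuple[str, str], tuple[GenomicInterval, ...]] = field(default_factory=dict)

    def _table(self, context: str) -> dict[tuple[str, str], tuple[GenomicInterval, ...]]:
        if context == "exonic":
            return self.exonic
        if context == "intronic":
            return self.intronic
        raise ValueError(f"unknown feature context {context!r}")

    def context_intervals(
        self, context: str, chrom: str, strand: str
    ) -> list[GenomicInterval]:
        """Feature intervals of one context on (chrom, strand).

        For an unstranded query strand ('.') the two strands' intervals
        are pooled and re-merged.
        """
        table = self._table(context)
        if strand != ".":
            return list(table.get((chrom, strand), ()))
        pooled = [iv for s in STRANDS for iv in table.get((chrom, s), ())]
        return merge(pooled) if pooled else []

    def all_intervals(self, context: str) -> list[GenomicInterval]:
        table = self._table(context)
        return [iv for key in sorted(table) for iv in table[key]]

    def index(self, context: str) -> IntervalIndex:
        return IntervalIndex(self.all_intervals(context))


def build_feature_space(genes: Iterable[GeneModel]) -> FeatureSpace:
    """Merge all exons and all between-exon gaps into disjoint exon/intron sets.

    Intronic bases that are exonic in an overlapping gene on the same
    (chrom, strand) are reassigned to the exonic set (exon precedence).
    """
    exons: list[GenomicInterval] = []
    introns: list[GenomicInterval] = []
    for gene in genes:
        exons.extend(gene.exons)
        introns.extend(gene.introns())

    space = FeatureSpace()
    ex_by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    in_by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in exons:
        ex_by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for iv in introns:
        in_by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for key, ivs in ex_by_key.items():
        space.exonic[key] = tuple(merge(ivs, strand_aware=True))
    for key, ivs in in_by_key.items():
        merged = merge(ivs, strand_aware=True)
        exonic_here = space.exonic.get(key, ())
        space.intronic[key] = tuple(subtract(merged, exonic_here))
    # drop keys emptied by exon precedence
    space.intronic = {k: v for k, v in space.intronic.items() if v}
    return space


def promoter_targets(
    peaks: Iterable[GenomicInterval],
    genes: Iterable[GeneModel],
    half_width: int = 500,
) -> set[str]:
    """Gene ids whose TSS +/- ``half_width`` window overlaps any peak.

    Windows are strand-agnostic since ChIP peaks carry no strand.
    """
    if half_width < 0:
        raise IntervalError(f"half_width must be >= 0, got {half_width}")
    unstranded_peaks = [
        GenomicInterval(p.chrom, p.start, p.end) for p in peaks
    ]
    idx = IntervalIndex(merge(unstranded_peaks))
    hits: set[str] = set()
    for gene in genes:
        lo = max(0, gene.tss - half_width)
        hi = gene.tss + half_width
        if hi <= lo:
            continue
        window = GenomicInterval(gene.chrom, lo, hi)
        if idx.overlaps(window, strand_aware=False):
            hits.add(gene.gene_id)
    return hits
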