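"""Constrained-permutation enrichment test for CLIP-site / splicing-region overlap.

Sites are classified as exonic or intronic against a merged feature space
(ambiguous sites randomly assigned), then repeatedly re-placed uniformly at
random within feature intervals of the same context, chromosome and strand,
never overlapping the original coordinates. The per-iteration overlap counts
form an empirical null against which a one-sided Monte Carlo p-value is
computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .events import ObservedOverlap, SpliceEvent, event_regions, observed_overlap
from .intervals import (
    FeatureSpace,
    GenomicInterval,
    IntervalIndex,
    expand,
    merge,
    strands_compatible,
)

__all__ = [
    "LabeledSite",
    "ClassifiedSites",
    "EnrichmentResult",
    "classify_sites",
    "constrained_shuffle",
    "monte_carlo_p",
    "permutation_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledSite:
    """A CLIP site with its assigned feature context."""

    site: GenomicInterval
    context: str  # "exonic" | "intronic"
    ambiguous_origin: bool = False


@dataclass(frozen=True)
class ClassifiedSites:
    labeled: tuple[LabeledSite, ...]
    intergenic: tuple[GenomicInterval, ...]  # overlap neither feature set


@dataclass
class EnrichmentResult:
    """Observed statistic, permutation null and Monte Carlo p-value."""

    observed: ObservedOverlap
    stat: str  # "sites" | "events"
    observed_stat: int
    null_counts: list[int]
    n_iter: int
    p_value: float
    fold_enrichment: float | None
    seed: int
    n_intergenic: int
    n_skipped_per_iter: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        null = np.asarray(self.null_counts, dtype=float)
        return {
            "stat": self.stat,
            "observed": {
                "n_events": self.observed.n_events,
                "n_events_hit": self.observed.n_events_hit,
                "fraction_events_hit": self.observed.fraction_events_hit,
                "n_sites_hit": self.observed.n_sites_hit,
            },
            "observed_stat": self.observed_stat,
            "n_iter": self.n_iter,
            "null_mean": float(null.mean()) if null.size else None,
            "null_sd": float(null.std(ddof=1)) if null.size > 1 else None,
            "null_quantiles": {
                q: float(np.quantile(null, float(q)))
                for q in ("0.025", "0.5", "0.975")
            }
            if null.size
            else {},
            "null_counts": [int(c) for c in self.null_counts],
            "p_value": self.p_value,
            "fold_enrichment": self.fold_enrichment,
            "seed": self.seed,
            "n_intergenic": self.n_intergenic,
            "n_skipped_per_iter": list(self.n_skipped_per_iter),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def classify_sites(
    sites: Sequence[GenomicInterval],
    space: FeatureSpace,
    rng: np.random.Generator,
) -> ClassifiedSites:
    """Assign each site an exonic or intronic context.

    Sites overlapping only one feature set take that context; sites
    overlapping both are ambiguous and assigned at random with probability
    equal to the exonic fraction among unambiguous sites (0.5 when there
    are none), preserving the observed context distribution. Sites
    overlapping neither set are returned separately and excluded from
    shuffling.
    """
    ex_idx = space.index("exonic")
    in_idx = space.index("intronic")
    flags: list[tuple[bool, bool]] = [
        (ex_idx.overlaps(s, strand_aware=True), in_idx.overlaps(s, strand_aware=True))
        for s in sites
    ]
    n_ex = sum(1 for e, i in flags if e and not i)
    n_in = sum(1 for e, i in flags if i and not e)
    p_exonic = n_ex / (n_ex + n_in) if (n_ex + n_in) else 0.5

    labeled: list[LabeledSite] = []
    intergenic: list[GenomicInterval] = []
    for site, (in_ex, in_in) in zip(sites, flags):
        if in_ex and in_in:
            context = "exonic" if rng.random() < p_exonic else "intronic"
            labeled.append(LabeledSite(site, context, ambiguous_origin=True))
        elif in_ex:
            labeled.append(LabeledSite(site, "exonic"))
        elif in_in:
            labeled.append(LabeledSite(site, "intronic"))
        else:
            intergenic.append(site)
    if intergenic:
        logger.info(
            "%d/%d sites overlap neither exonic nor intronic space; "
            "excluded from shuffling", len(intergenic), len(sites),
        )
    return ClassifiedSites(tuple(labeled), tuple(intergenic))


class _ExcludeIndex:
    """Per-(chrom, query strand) sorted disjoint arrays of the original sites."""

    def __init__(self, original: Sequence[GenomicInterval]):
        self._arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._original = list(original)

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        key = (chrom, strand)
        if key not in self._arrays:
            ivs = [
                GenomicInterval(iv.chrom, iv.start, iv.end)
                for iv in self._original
                if iv.chrom == chrom and strands_compatible(iv.strand, strand)
            ]
            merged = merge(ivs)
            self._arrays[key] = (
                np.asarray([iv.start for iv in merged], dtype=np.int64),
                np.asarray([iv.end for iv in merged], dtype=np.int64),
            )
        return self._arrays[key]


def _overlaps_arrays(
    starts: np.ndarray, ends: np.ndarray, q_start: np.ndarray, q_end: np.ndarray
) -> np.ndarray:
    """Vectorized boolean overlap of queries against sorted disjoint intervals."""
    if starts.size == 0:
        return np.zeros(q_start.shape, dtype=bool)
    i = np.searchsorted(starts, q_end, side="left")
    hit = i > 0
    prev = np.maximum(i - 1, 0)
    hit &= ends[prev] > q_start
    return hit


def constrained_shuffle(
    labeled: Sequence[LabeledSite],
    space: FeatureSpace,
    rng: np.random.Generator,
    exclude: Sequence[GenomicInterval] | _ExcludeIndex = (),
    max_retries: int = 100,
) -> tuple[list[GenomicInterval], int]:
    """Re-place every labeled site uniformly at random under four constraints:
    same length, same chromosome, same strand, same feature context, and no
    overlap with ``exclude`` (the original site set).

    Placement is uniform over the cumulative valid-start space of all
    feature intervals able to contain the site, with rejection sampling
    against ``exclude``. Sites with no admissible placement after
    ``max_retries`` rounds are skipped (logged); returns the shuffled
    intervals and the skip count.
    """
    if not isinstance(exclude, _ExcludeIndex):
        exclude = _ExcludeIndex(exclude)

    placed: list[GenomicInterval | None] = [None] * len(labeled)
    n_skipped = 0

    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, ls in enumerate(labeled):
        groups.setdefault((ls.site.chrom, ls.site.strand, ls.context), []).append(i)

    for (chrom, strand, context) in sorted(groups):
        idxs = groups[(chrom, strand, context)]
        feats = space.context_intervals(context, chrom, strand)
        site_lens = np.asarray([labeled[i].site.length for i in idxs], dtype=np.int64)
        if not feats:
            n_skipped += len(idxs)
            logger.warning(
                "no %s feature intervals on %s/%s; skipping %d site(s)",
                context, chrom, strand, len(idxs),
            )
            continue
        f_starts = np.asarray([iv.start for iv in feats], dtype=np.int64)
        f_lens = np.asarray([iv.length for iv in feats], dtype=np.int64)
        # valid start positions per (site, feature interval)
        caps = np.clip(f_lens[None, :] - site_lens[:, None] + 1, 0, None)
        cum = np.cumsum(caps, axis=1)
        totals = cum[:, -1]
        ex_starts, ex_ends = exclude.arrays(chrom, strand)

        fits = totals > 0
        n_skipped += int((~fits).sum())
        if (~fits).any():
            logger.warning(
                "%d site(s) too long for any %s interval on %s/%s; skipped",
                int((~fits).sum()), context, chrom, strand,
            )
        active = np.flatnonzero(fits)
        chosen = np.full(len(idxs), -1, dtype=np.int64)
        for _ in range(max_retries):
            if active.size == 0:
                break
            u = rng.random(active.size) * totals[active]
            # row-wise searchsorted into each site's cumulative capacity
            cact = cum[active]
            j = (u[:, None] >= cact).sum(axis=1)
            prev = np.where(
                j > 0,
                np.take_along_axis(cact, np.maximum(j - 1, 0)[:, None], axis=1).ravel(),
                0,
            )
            offset = np.floor(u - prev).astype(np.int64)
            starts = f_starts[j] + offset
            ends = starts + site_lens[active]
            bad = _overlaps_arrays(ex_starts, ex_ends, starts, ends)
            ok = ~bad
            chosen[active[ok]] = starts[ok]
            active = active[bad]
        # exact fallback: enumerate the admissible start segments for sites the
        # rejection rounds could not place (e.g. exclude covers nearly all space)
        for a in active:
            length = int(site_lens[a])
            segments: list[tuple[int, int]] = []  # half-open ranges of valid starts
            for fs, fl in zip(f_starts, f_lens):
                if fl < length:
                    continue
                lo, hi = int(fs), int(fs + fl - length + 1)
                pos = lo
                for es, ee in zip(ex_starts, ex_ends):
                    # starts in [es - length + 1, ee) collide with this exclude interval
                    blk_lo, blk_hi = int(es) - length + 1, int(ee)
                    if blk_hi <= pos or blk_lo >= hi:
                        continue
                    if blk_lo > pos:
                        segments.append((pos, min(blk_lo, hi)))
                    pos = max(pos, blk_hi)
                    if pos >= hi:
                        break
                if pos < hi:
                    segments.append((pos, hi))
            total = sum(hi - lo for lo, hi in segments)
            if total == 0:
                n_skipped += 1
                logger.warning(
                    "site on %s/%s (%s, length %d) has no placement clear of the "
                    "original coordinates; skipped", chrom, strand, context, length,
                )
                continue
            pick = int(rng.integers(0, total))
            for lo, hi in segments:
                if pick < hi - lo:
                    chosen[a] = lo + pick
                    break
                pick -= hi - lo
        for local_i, start in enumerate(chosen):
            if start < 0:
                continue
            src = labeled[idxs[local_i]].site
            placed[idxs[local_i]] = GenomicInterval(
                chrom, int(start), int(start) + src.length, src.strand,
                score=src.score, name=src.name,
            )
    return [iv for iv in placed if iv is not None], n_skipped


def monte_carlo_p(observed_count: float, null_counts: Sequence[float]) -> float:
    """One-sided (enrichment) Monte Carlo p with add-one correction:
    ``p = (1 + #{null >= observed}) / (N + 1)``; ties count."""
    if len(null_counts) == 0:
        raise ValueError("null_counts must be non-empty")
    n_ge = sum(1 for c in null_counts if c >= observed_count)
    return (1 + n_ge) / (len(null_counts) + 1)


class _RegionUnionIndex:
    """Union of expanded splicing regions as per-(chrom, query strand) arrays."""

    def __init__(self, regions: Sequence[GenomicInterval], strand_aware: bool):
        self.strand_aware = strand_aware
        self._arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._regions = list(regions)

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        if not self.strand_aware:
            strand = "."
        key = (chrom, strand)
        if key not in self._arrays:
            ivs = [
                GenomicInterval(iv.chrom, iv.start, iv.end)
                for iv in self._regions
                if iv.chrom == chrom
                and (not self.strand_aware or strands_compatible(iv.strand, strand))
            ]
            merged = merge(ivs)
            self._arrays[key] = (
                np.asarray([iv.start for iv in merged], dtype=np.int64),
                np.asarray([iv.end for iv in merged], dtype=np.int64),
            )
        return self._arrays[key]

    def count_hits(self, sites: Sequence[GenomicInterval]) -> int:
        by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
        for s in sites:
            by_key.setdefault((s.chrom, s.strand), []).append(s)
        total = 0
        for (chrom, strand), group in by_key.items():
            starts, ends = self.arrays(chrom, strand)
            q_start = np.asarray([s.start for s in group], dtype=np.int64)
            q_end = np.asarray([s.end for s in group], dtype=np.int64)
            total += int(_overlaps_arrays(starts, ends, q_start, q_end).sum())
        return total


def permutation_enrichment(
    regions_source: Sequence[SpliceEvent],
    sites: Sequence[GenomicInterval],
    space: FeatureSpace,
    sizes: Mapping[str, int],
    n_iter: int = 500,
    flank: int = 200,
    seed: int = 0,
    stat: str = "sites",
    strand_aware: bool = True,
    reclassify_each_iter: bool = False,
    max_retries: int = 100,
) -> EnrichmentResult:
    """Full permutation test of CLIP-site enrichment in splicing-associated regions.

    ``stat`` selects the per-iteration overlap count: ``"sites"`` (shuffled
    sites overlapping the union of expanded regions; default) or
    ``"events"`` (events with >= 1 shuffled site in their regions). The
    observed statistic uses the true site set, including any intergenic
    sites that the shuffle cannot re-place. Identical seeds give identical
    results; iterations draw from per-iteration child seeds of the master
    seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if stat not in ("sites", "events"):
        raise ValueError(f"unknown stat {stat!r}")

    obs = observed_overlap(regions_source, sites, sizes, flank=flank, strand_aware=strand_aware)
    observed_stat = obs.n_sites_hit if stat == "sites" else obs.n_events_hit

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter + 1)
    rng_classify = np.random.default_rng(children[0])
    classified = classify_sites(sites, space, rng_classify)
    exclude = _ExcludeIndex(sites)

    expanded_regions: list[GenomicInterval] = []
    per_event_indexes: list[IntervalIndex] = []
    for ev in regions_source:
        ev_expanded = [expand(iv, sizes, flank) for iv in event_regions(ev)]
        merged = merge(ev_expanded, strand_aware=strand_aware and ev.strand != ".")
        expanded_regions.extend(merged)
        if stat == "events":
            per_event_indexes.append(IntervalIndex(merged))
    union = _RegionUnionIndex(expanded_regions, strand_aware=strand_aware)

    null_counts: list[int] = []
    skips: list[int] = []
    for it in range(n_iter):
        rng_it = np.random.default_rng(children[it + 1])
        if reclassify_each_iter:
            classified_it = classify_sites(sites, space, rng_it)
        else:
            classified_it = classified
        shuffled, n_skipped = constrained_shuffle(
            classified_it.labeled, space, rng_it, exclude, max_retries=max_retries
        )
        if classified_it.labeled and not shuffled:
            raise RuntimeError(f"iteration {it}: every site was skipped during shuffling")
        if stat == "sites":
            count = union.count_hits(shuffled)
        else:
            count = sum(
                1
                for idx in per_event_indexes
                if any(idx.overlaps(s, strand_aware=strand_aware) for s in shuffled)
            )
        null_counts.append(count)
        skips.append(n_skipped)
        logger.debug("iteration %d: null count %d (%d skipped)", it, count, n_skipped)

    p = monte_carlo_p(observed_stat, null_counts)
    null_mean = float(np.mean(null_counts))
    fold = observed_stat / null_mean if null_mean > 0 else None
    return EnrichmentResult(
        observed=obs,
        stat=stat,
        observed_stat=observed_stat,
        null_counts=null_counts,
        n_iter=n_iter,
        p_value=p,
        fold_enrichment=fold,
        seed=seed,
        n_intergenic=len(classified.intergenic),
        n_skipped_per_iter=skips,
    )
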