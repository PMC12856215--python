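"""rMATS-style alternative-splicing events: parsing, significance filtering,
splicing-associated region extraction and observed CLIP-overlap statistics.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalError,
    IntervalIndex,
    expand,
    merge,
)

__all__ = [
    "EVENT_TYPES",
    "SpliceEvent",
    "ObservedOverlap",
    "read_rmats_table",
    "write_rmats_table",
    "filter_events",
    "event_regions",
    "observed_overlap",
    "event_type_counts",
    "delta_psi_matrix",
    "event_key",
]

EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")

# rMATS coordinate column layout per event type: (target columns, flank columns),
# each a list of (start_col, end_col) pairs with 0-based starts.
_RMATS_COORDS: dict[str, tuple[list[tuple[str, str]], list[tuple[str, str]]]] = {
    "SE": (
        [("exonStart_0base", "exonEnd")],
        [("upstreamES", "upstreamEE"), ("downstreamES", "downstreamEE")],
    ),
    "RI": (
        [("riExonStart_0base", "riExonEnd")],
        [("upstreamES", "upstreamEE"), ("downstreamES", "downstreamEE")],
    ),
    "MXE": (
        [("1stExonStart_0base", "1stExonEnd"), ("2ndExonStart_0base", "2ndExonEnd")],
        [("upstreamES", "upstreamEE"), ("downstreamES", "downstreamEE")],
    ),
    # Long exon spans variable + common region; flanking exon is the shared one.
    "A5SS": ([("longExonStart_0base", "longExonEnd")], [("flankingES", "flankingEE")]),
    "A3SS": ([("longExonStart_0base", "longExonEnd")], [("flankingES", "flankingEE")]),
}


@dataclass(frozen=True)
class SpliceEvent:
    """One differential alternative-splicing event in rMATS terms."""

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    target_coords: tuple[GenomicInterval, ...]
    flank_coords: tuple[GenomicInterval, ...]
    psi_group1: float
    psi_group2: float
    delta_psi: float
    p_value: float
    fdr: float
    inc_levels1: tuple[float | None, ...] = field(default=(), compare=False)
    inc_levels2: tuple[float | None, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        for psi in (self.psi_group1, self.psi_group2):
            if not math.isnan(psi) and not 0.0 <= psi <= 1.0:
                raise ValueError(f"event {self.event_id}: PSI {psi} outside [0, 1]")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"event {self.event_id}: FDR {self.fdr} outside [0, 1]")
        n_targets = len(self.target_coords)
        expected = 2 if self.event_type == "MXE" else 1
        if n_targets != expected:
            raise ValueError(
                f"event {self.event_id}: {self.event_type} requires {expected} "
                f"target interval(s), got {n_targets}"
            )
        for iv in (*self.target_coords, *self.flank_coords):
            if iv.chrom != self.chrom:
                raise ValueError(f"event {self.event_id}: coordinate on wrong chromosome")


@dataclass(frozen=True)
class ObservedOverlap:
    """Observed CLIP-site / splicing-region overlap summary."""

    n_events: int
    n_events_hit: int
    n_sites_hit: int

    @property
    def fraction_events_hit(self) -> float:
        return self.n_events_hit / self.n_events if self.n_events else 0.0


def event_key(event: SpliceEvent) -> tuple:
    """Identity of an event across contrasts: type, chrom, strand and target coordinates."""
    return (
        event.event_type,
        event.chrom,
        event.strand,
        tuple((iv.start, iv.end) for iv in event.target_coords),
    )


def _parse_inc_levels(cell: object) -> tuple[float | None, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    parts = str(cell).split(",")
    return tuple(None if p.strip() in ("NA", "", "nan") else float(p) for p in parts)


def _mean_inc(levels: tuple[float | None, ...]) -> float:
    vals = [v for v in levels if v is not None]
    return sum(vals) / len(vals) if vals else float("nan")


def read_rmats_table(path: str | os.PathLike, event_type: str) -> list[SpliceEvent]:
    """Parse one rMATS junction-count output table (e.g. ``SE.MATS.JC.txt`` layout).

    Replicate inclusion levels are comma-separated with ``NA`` for missing;
    group means ignore missing entries. Coordinates are 0-based half-open.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    target_cols, flank_cols = _RMATS_COORDS[event_type]
    required = (
        ["ID", "GeneID", "chr", "strand", "IncLevel1", "IncLevel2",
         "IncLevelDifference", "PValue", "FDR"]
        + [c for pair in target_cols + flank_cols for c in pair]
    )
    for col in required:
        if col not in df.columns:
            raise IntervalError(f"{path}: missing required rMATS column {col!r}")
    events: list[SpliceEvent] = []
    for _, row in df.iterrows():
        chrom, strand = row["chr"], row["strand"]
        try:
            fdr = float(row["FDR"])
        except (TypeError, ValueError):
            raise IntervalError(f"{path}: non-numeric FDR {row['FDR']!r} for event {row['ID']}")
        inc1 = _parse_inc_levels(row["IncLevel1"])
        inc2 = _parse_inc_levels(row["IncLevel2"])
        targets = tuple(
            GenomicInterval(chrom, int(row[s]), int(row[e]), strand)
            for s, e in target_cols
        )
        flanks = tuple(
            GenomicInterval(chrom, int(row[s]), int(row[e]), strand)
            for s, e in flank_cols
        )
        events.append(
            SpliceEvent(
                event_id=str(row["ID"]),
                event_type=event_type,
                gene_id=str(row["GeneID"]),
                chrom=chrom,
                strand=strand,
                target_coords=targets,
                flank_coords=flanks,
                psi_group1=_mean_inc(inc1),
                psi_group2=_mean_inc(inc2),
                delta_psi=float(row["IncLevelDifference"]),
                p_value=float(row["PValue"]),
                fdr=fdr,
                inc_levels1=inc1,
                inc_levels2=inc2,
            )
        )
    return events


def _fmt_inc(levels: tuple[float | None, ...]) -> str:
    return ",".join("NA" if v is None else format(v, ".6g") for v in levels)


def write_rmats_table(
    path: str | os.PathLike, events: Sequence[SpliceEvent], event_type: str
) -> None:
    """Write events of one type in the rMATS dialect :func:`read_rmats_table` accepts."""
    target_cols, flank_cols = _RMATS_COORDS[event_type]
    coord_cols = [c for pair in target_cols + flank_cols for c in pair]
    header = ["ID", "GeneID", "geneSymbol", "chr", "strand", *coord_cols,
              "IncLevel1", "IncLevel2", "IncLevelDifference", "PValue", "FDR"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for ev in events:
            if ev.event_type != event_type:
                raise ValueError(f"event {ev.event_id} has type {ev.event_type}, expected {event_type}")
            coords: list[str] = []
            for iv, _pair in zip(ev.target_coords, target_cols):
                coords.extend([str(iv.start), str(iv.end)])
            for iv, _pair in zip(ev.flank_coords, flank_cols):
                coords.extend([str(iv.start), str(iv.end)])
            row = [
                ev.event_id, ev.gene_id, ev.gene_id, ev.chrom, ev.strand, *coords,
                _fmt_inc(ev.inc_levels1), _fmt_inc(ev.inc_levels2),
                format(ev.delta_psi, ".6g"), format(ev.p_value, ".6g"), format(ev.fdr, ".6g"),
            ]
            fh.write("\t".join(row) + "\n")


def filter_events(
    events: Iterable[SpliceEvent],
    max_fdr: float = 0.05,
    min_abs_dpsi: float = 0.0,
) -> list[SpliceEvent]:
    """Keep events with ``fdr < max_fdr`` and ``|delta_psi| > min_abs_dpsi``.

    Both inequalities are strict, so FDR exactly at the threshold is excluded.
    With the default ``min_abs_dpsi = 0`` this reproduces FDR-only event lists.
    """
    return [
        ev for ev in events
        if ev.fdr < max_fdr and abs(ev.delta_psi) > min_abs_dpsi
    ]


def event_regions(event: SpliceEvent) -> list[GenomicInterval]:
    """The splicing-associated intervals of one event: target exon/intron plus
    flanking exons, duplicates removed, input order preserved."""
    seen: set[tuple[int, int]] = set()
    out: list[GenomicInterval] = []
    for iv in (*event.target_coords, *event.flank_coords):
        key = (iv.start, iv.end)
        if key not in seen:
            seen.add(key)
            out.append(iv)
    return out


def observed_overlap(
    events: Sequence[SpliceEvent],
    sites: Sequence[GenomicInterval],
    sizes: Mapping[str, int],
    flank: int = 200,
    strand_aware: bool = True,
) -> ObservedOverlap:
    """Count events with >= 1 binding site in their expanded regions and
    sites overlapping >= 1 expanded region.

    Each event's regions are widened by ``flank`` bp and merged per event
    before intersection; an unstranded site matches either strand under
    ``strand_aware``.
    """
    per_event_indexes: list[IntervalIndex] = []
    all_regions: list[GenomicInterval] = []
    for ev in events:
        expanded = [expand(iv, sizes, flank) for iv in event_regions(ev)]
        merged = merge(expanded, strand_aware=strand_aware and ev.strand != ".")
        per_event_indexes.append(IntervalIndex(merged))
        all_regions.extend(merged)
    n_events_hit = 0
    for idx in per_event_indexes:
        if any(idx.overlaps(site, strand_aware=strand_aware) for site in sites):
            n_events_hit += 1
    union_index = IntervalIndex(all_regions)
    n_sites_hit = sum(
        1 for site in sites if union_index.overlaps(site, strand_aware=strand_aware)
    )
    return ObservedOverlap(
        n_events=len(events), n_events_hit=n_events_hit, n_sites_hit=n_sites_hit
    )


def event_type_counts(events: Iterable[SpliceEvent]) -> dict[str, int]:
    """Breakdown of events by type; every type appears, absent ones with 0."""
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        counts[ev.event_type] += 1
    return counts


def delta_psi_matrix(
    contrast_events: Mapping[str, Sequence[SpliceEvent]]
) -> pd.DataFrame:
    """Event x contrast table of delta-PSI values.

    Rows are the union of event keys across contrasts; a cell is NaN when
    the event is absent from that contrast (absence, not zero effect).
    """
    columns = list(contrast_events)
    cells: dict[tuple, dict[str, float]] = {}
    for contrast, events in contrast_events.items():
        seen: set[tuple] = set()
        for ev in events:
            key = event_key(ev)
            if key in seen:
                raise ValueError(
                    f"duplicate event key in contrast {contrast!r}: {key}"
                )
            seen.add(key)
            cells.setdefault(key, {})[contrast] = ev.delta_psi
    index = sorted(cells)
    data = {
        contrast: [cells[key].get(contrast, float("nan")) for key in index]
        for contrast in columns
    }
    labels = [
        f"{key[0]}|{key[1]}|{key[2]}|" + ";".join(f"{s}-{e}" for s, e in key[3])
        for key in index
    ]
    return pd.DataFrame(data, index=labels, columns=columns)
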