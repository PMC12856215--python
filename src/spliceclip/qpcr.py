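"""qPCR cycle-threshold statistics.

Relative expression and the exon inclusion/exclusion ratio use the base-2
delta-Ct convention with the reference (GAPDH) Ct minus the target Ct, so
higher target expression gives a larger delta-Ct. ChIP/RIP occupancy is
expressed as percent enrichment of input.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CtRecord",
    "read_ct_table",
    "aggregate_ct",
    "delta_ct",
    "inclusion_ratio",
    "relative_expression",
    "percent_input",
    "estimate_inclusion_ratio",
    "group_compare",
]

logger = logging.getLogger(__name__)

TECH_SD_WARN_CYCLES = 0.5


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: sample, primer target, biological and technical replicate."""

    sample_id: str
    target: str
    bio_rep: int
    tech_rep: int
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(
                f"{self.sample_id}/{self.target} bio {self.bio_rep} tech {self.tech_rep}: "
                f"Ct must be finite and > 0, got {self.ct}"
            )


def read_ct_table(path: str | os.PathLike) -> list[CtRecord]:
    """Read a tab-separated Ct table: sample_id, target, bio_rep, tech_rep, ct."""
    records: list[CtRecord] = []
    keys: set[tuple] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "target", "bio_rep", "tech_rep", "ct"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            rec = CtRecord(f[0], f[1], int(f[2]), int(f[3]), float(f[4]))
            key = (rec.sample_id, rec.target, rec.bio_rep, rec.tech_rep)
            if key in keys:
                raise ValueError(f"{path}:{lineno}: duplicate record {key}")
            keys.add(key)
            records.append(rec)
    return records


def write_ct_table(path: str | os.PathLike, records: Iterable[CtRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttarget\tbio_rep\ttech_rep\tct\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.target}\t{r.bio_rep}\t{r.tech_rep}\t{r.ct:.6g}\n")


def aggregate_ct(cts: Sequence[float]) -> float:
    """Mean Ct across technical replicates (on the cycle scale).

    Warns when the technical SD exceeds 0.5 cycles — a sign of pipetting or
    amplification trouble — but never drops wells.
    """
    if len(cts) == 0:
        raise ValueError("at least one technical replicate required")
    arr = np.asarray(cts, dtype=float)
    if arr.size > 1 and arr.std(ddof=1) > TECH_SD_WARN_CYCLES:
        logger.warning(
            "technical-replicate SD %.2f cycles exceeds %.1f", arr.std(ddof=1),
            TECH_SD_WARN_CYCLES,
        )
    return float(arr.mean())


def delta_ct(ct_reference: float, ct_target: float) -> float:
    """delta-Ct = reference Ct - target Ct (larger means more target)."""
    return ct_reference - ct_target


def inclusion_ratio(dct_inclusion: float, dct_exclusion: float) -> float:
    """Exon inclusion/exclusion transcript ratio: 2^(dCt_inclusion - dCt_exclusion)."""
    return 2.0 ** (dct_inclusion - dct_exclusion)


def relative_expression(dct: float) -> float:
    """Expression relative to the reference gene: 2^dCt."""
    return 2.0 ** dct


def percent_input(ct_input: float, ct_ip: float, input_fraction: float) -> float:
    """ChIP/RIP percent enrichment of input.

    ``input_fraction`` is the proportion of IP material the measured input
    aliquot represents (e.g. 0.01 for a 1% input); the result is
    ``100 * input_fraction * 2^(ct_input - ct_ip)``.
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    return 100.0 * input_fraction * 2.0 ** (ct_input - ct_ip)


def estimate_inclusion_ratio(
    records: Sequence[CtRecord],
    reference: str = "GAPDH",
    inclusion: str = "inclusion",
    exclusion: str = "exclusion",
) -> dict:
    """Per-biological-replicate inclusion/exclusion ratios from a Ct table.

    Technical replicates are averaged on the Ct scale per (bio_rep, target),
    each target is normalized to the reference (delta-Ct), and the ratio is
    computed per biological replicate. Returns the per-replicate ratios plus
    their mean and SD.
    """
    by_bio: dict[int, dict[str, list[float]]] = {}
    for rec in records:
        by_bio.setdefault(rec.bio_rep, {}).setdefault(rec.target, []).append(rec.ct)
    ratios: dict[int, float] = {}
    for bio, targets in sorted(by_bio.items()):
        missing = [t for t in (reference, inclusion, exclusion) if t not in targets]
        if missing:
            raise ValueError(f"bio_rep {bio}: missing target(s) {missing}")
        ref_ct = aggregate_ct(targets[reference])
        dct_inc = delta_ct(ref_ct, aggregate_ct(targets[inclusion]))
        dct_exc = delta_ct(ref_ct, aggregate_ct(targets[exclusion]))
        ratios[bio] = inclusion_ratio(dct_inc, dct_exc)
    vals = np.asarray(list(ratios.values()))
    return {
        "per_bio_rep": ratios,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
    }


def sidak_adjust(p: float, n_comparisons: int) -> float:
    """Sidak family-wise adjustment of one raw p over ``n_comparisons`` tests."""
    return 1.0 - (1.0 - p) ** n_comparisons


def group_compare(
    groups: Mapping[str, Sequence[float]],
    design: str = "pairwise",
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> dict:
    """Compare per-condition biological-replicate values.

    ``design="pairwise"`` runs a two-tailed unpaired two-sample t-test
    (exactly two groups). ``design="multi"`` runs a one-way ANOVA followed
    by Sidak-adjusted pairwise t-tests for the requested ``comparisons``
    (all pairs by default). Returns raw and adjusted p-values keyed by
    comparison.
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs >= 2 biological replicates")
    if design == "pairwise":
        if len(names) != 2:
            raise ValueError("pairwise design requires exactly 2 groups")
        a, b = names
        t = stats.ttest_ind(groups[a], groups[b])
        return {"comparisons": {(a, b): {"p_raw": float(t.pvalue), "p_adj": float(t.pvalue)}}}
    if design != "multi":
        raise ValueError(f"unknown design {design!r}")
    if len(names) < 2:
        raise ValueError("multi design requires >= 2 groups")
    anova = stats.f_oneway(*(groups[n] for n in names))
    pairs = list(comparisons) if comparisons is not None else list(combinations(names, 2))
    m = len(pairs)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in pairs:
        t = stats.ttest_ind(groups[a], groups[b])
        p_raw = float(t.pvalue)
        out[(a, b)] = {"p_raw": p_raw, "p_adj": min(1.0, sidak_adjust(p_raw, m))}
    return {"anova_p": float(anova.pvalue), "comparisons": out}
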