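"""Independent brute-force oracles used to validate the fast implementations.

Everything here works on explicit per-base boolean arrays or naive O(n^2)
enumeration, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np

from spliceclip.intervals import GenomicInterval


def base_set(intervals, chrom_len: int, chrom: str, strand: str | None = None) -> np.ndarray:
    """Boolean occupancy array over every base of one chromosome (and strand)."""
    occ = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        if strand is not None and iv.strand != strand:
            continue
        occ[iv.start : iv.end] = True
    return occ


def covered_bases(intervals, chrom_len: int, chrom: str, strand: str | None = None) -> int:
    return int(base_set(intervals, chrom_len, chrom, strand).sum())


def brute_overlaps(query: GenomicInterval, subjects, strand_aware: bool) -> bool:
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        if strand_aware:
            qa, sa = query.strand, s.strand
            if qa != "." and sa != "." and qa != sa:
                continue
        if max(query.start, s.start) < min(query.end, s.end):
            return True
    return False


def brute_consensus(replicate_sets, strand_aware: bool):
    """Keep sites overlapping >= 1 site in every other replicate; return the
    union as a list (caller compares base sets)."""
    kept = []
    for i, sites in enumerate(replicate_sets):
        for iv in sites:
            ok = True
            for j, other in enumerate(replicate_sets):
                if j == i:
                    continue
                if not brute_overlaps(iv, other, strand_aware):
                    ok = False
                    break
            if ok:
                kept.append(iv)
    return kept


def brute_venn(named_sets: dict) -> dict:
    regions: dict[frozenset, set] = {}
    for item in set().union(*named_sets.values()):
        sig = frozenset(n for n, s in named_sets.items() if item in s)
        regions.setdefault(sig, set()).add(item)
    return regions


def brute_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by direct definition."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * n / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj
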