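"""Condition-dependency set logic over DEG tables and splice-event lists:
significance filtering, Venn partitions, uniquely-regulated (co-dependent)
sets and DEG/AS overlap classification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import SpliceEvent

__all__ = [
    "DEGRecord",
    "read_deg_table",
    "filter_degs",
    "venn_partition",
    "codependent_set",
    "deg_as_overlap",
    "as_gene_set",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result versus the reference condition."""

    gene_id: str
    log2fc: float
    p_value: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.gene_id}: p-value {self.p_value} outside [0, 1]")
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


def read_deg_table(path: str | os.PathLike) -> list[DEGRecord]:
    """Read a DESeq2-style results table (gene_id, log2FoldChange, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t")
    colmap = {}
    for want, aliases in {
        "gene_id": ("gene_id", "gene", "GeneID"),
        "log2fc": ("log2FoldChange", "log2fc", "log2FC"),
        "p_value": ("pvalue", "p_value", "PValue"),
        "padj": ("padj", "p_adj", "FDR"),
    }.items():
        for a in aliases:
            if a in df.columns:
                colmap[want] = a
                break
        else:
            raise ValueError(f"{path}: missing column for {want} (tried {aliases})")
    return [
        DEGRecord(
            gene_id=str(row[colmap["gene_id"]]),
            log2fc=float(row[colmap["log2fc"]]),
            p_value=float(row[colmap["p_value"]]),
            padj=float(row[colmap["padj"]]),
        )
        for _, row in df.iterrows()
    ]


def write_deg_table(path: str | os.PathLike, records: Sequence[DEGRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2FoldChange\tpvalue\tpadj\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.p_value:.6g}\t{r.padj:.6g}\n")


def filter_degs(
    records: Iterable[DEGRecord],
    max_padj: float = 0.05,
    min_abs_log2fc: float = 0.58,
) -> set[str]:
    """Genes with ``padj < max_padj`` and ``|log2fc| > min_abs_log2fc`` (both strict).

    The default fold-change cut corresponds to a 1.5-fold absolute change.
    Duplicate gene ids are an error — a results table has one row per gene.
    """
    seen: set[str] = set()
    kept: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in DEG table")
        seen.add(rec.gene_id)
        if rec.padj < max_padj and abs(rec.log2fc) > min_abs_log2fc:
            kept.add(rec.gene_id)
    return kept


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, set]:
    """Partition the union of the input sets by membership signature.

    Keys are frozensets of contrast names; every identifier lands in exactly
    one region, so regions are pairwise disjoint and their union equals the
    union of the inputs. Only non-empty regions are returned.
    """
    if len(sets) < 2:
        raise ValueError("venn_partition requires >= 2 named sets")
    regions: dict[frozenset, set] = {}
    universe = set().union(*sets.values())
    for item in universe:
        signature = frozenset(name for name, s in sets.items() if item in s)
        regions.setdefault(signature, set()).add(item)
    return regions


def codependent_set(sets: Mapping[str, set], target: str) -> set:
    """Identifiers regulated only under the ``target`` contrast.

    This is the "uniquely regulated" selection: present in the target's set
    and absent from every other contrast's set.
    """
    if target not in sets:
        raise KeyError(f"unknown target contrast {target!r}; have {sorted(sets)}")
    out = set(sets[target])
    for name, s in sets.items():
        if name != target:
            out -= s
    return out


def deg_as_overlap(deg_genes: set, as_genes: set) -> dict:
    """Classify genes as DEG-only, AS-only or both, with percentages of the union."""
    if not deg_genes and not as_genes:
        raise ValueError("both gene sets are empty")
    both = deg_genes & as_genes
    deg_only = deg_genes - as_genes
    as_only = as_genes - deg_genes
    n_union = len(deg_only) + len(as_only) + len(both)
    return {
        "deg_only": deg_only,
        "as_only": as_only,
        "both": both,
        "pct_non_overlapping": 100.0 * (len(deg_only) + len(as_only)) / n_union,
        "pct_both": 100.0 * len(both) / n_union,
    }


def as_gene_set(events: Iterable[SpliceEvent]) -> set[str]:
    """Distinct source genes of (already significance-filtered) splice events."""
    out: set[str] = set()
    for ev in events:
        if not ev.gene_id:
            raise ValueError(f"event {ev.event_id} lacks a gene_id")
        out.add(ev.gene_id)
    return out
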