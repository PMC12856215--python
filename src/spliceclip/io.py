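"""Readers and writers for the plain-text formats the pipeline consumes.

BED6 (3-6 columns), two-column chrom-sizes files and a minimal exon
table (gene_id, chrom, strand, exon_start, exon_end) for gene models.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

from .intervals import GeneModel, GenomicInterval, IntervalError

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_exon_table",
    "write_exon_table",
]


def _is_comment(line: str) -> bool:
    return line.startswith("#") or line.startswith("track") or line.startswith("browser")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a 3-6 column BED file; '#'/'track'/'browser' lines are skipped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_comment(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, score=score, name=name))
    return out


def write_bed(path: str | os.PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or _is_comment(line):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise IntervalError(f"{path}:{lineno}: expected 'name<TAB>length'")
            length = int(fields[1])
            if length < 1:
                raise IntervalError(f"{path}:{lineno}: chromosome length must be >= 1")
            sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(path: str | os.PathLike, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_exon_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read a minimal exon table: gene_id, chrom, strand, exon_start, exon_end.

    A header line is optional (detected by a non-integer fourth column).
    Rows for one gene need not be contiguous; exons are sorted per gene.
    """
    rows: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_comment(line):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise IntervalError(f"{path}:{lineno}: expected 5 tab-separated columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise IntervalError(f"{path}:{lineno}: non-integer exon coordinates")
            gene_id = fields[0]
            if gene_id not in rows:
                order.append(gene_id)
            rows.setdefault(gene_id, []).append((fields[1], fields[2], start, end))
    genes: list[GeneModel] = []
    for gene_id in order:
        recs = sorted(rows[gene_id], key=lambda r: r[2])
        chrom, strand = recs[0][0], recs[0][1]
        exons = tuple(
            GenomicInterval(chrom, s, e, strand) for _, _, s, e in recs
        )
        genes.append(GeneModel(gene_id, chrom, strand, exons))
    return genes


def write_exon_table(path: str | os.PathLike, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texon_start\texon_end\n")
        for gene in genes:
            for ex in gene.exons:
                fh.write(f"{gene.gene_id}\t{gene.chrom}\t{gene.strand}\t{ex.start}\t{ex.end}\n")
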