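"""Synthetic inputs for every pipeline stage, with known ground truth.

Generates toy genomes/gene models, rMATS-style differential-splicing
tables, replicated CLIP interval files with controllable planted
enrichment, DESeq2-style DEG tables and qPCR Ct tables. Every generator
is a pure function of its configuration and RNG, so identical seeds give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clip import ClipReplicate
from .events import EVENT_TYPES, SpliceEvent
from .intervals import FeatureSpace, GeneModel, GenomicInterval
from .qpcr import CtRecord
from .sets import DEGRecord

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_events",
    "simulate_clip",
    "simulate_deg_table",
    "simulate_ct",
]


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults give a toy scale that keeps the
    full suite fast on one CPU."""

    seed: int = 0
    # genome
    n_chrom: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1500)
    # splice events
    n_events: dict[str, int] = field(
        default_factory=lambda: {"SE": 200, "RI": 100, "MXE": 60, "A5SS": 70, "A3SS": 70}
    )
    prop_signal: float = 0.3
    dpsi_effect: float = 0.3
    n_replicates: int = 3
    psi_noise_sd: float = 0.2  # logit scale
    # CLIP sites
    n_sites: int = 1000
    site_length: tuple[int, int] = (20, 60)
    enrichment: float = 0.0
    n_clip_replicates: int = 2
    replicate_jitter: int = 5
    noise_sites_per_replicate: int = 50
    score_range: tuple[int, int] = (10, 100)
    # DEG
    deg_effect: float = 1.0
    deg_se: float = 0.15
    prop_signal_deg: float = 0.2
    # qPCR
    ct_bio_reps: int = 3
    ct_tech_reps: int = 3
    ct_noise_sd: float = 0.2

    def validate(self) -> None:
        if min(self.n_chrom, self.chrom_length, self.n_genes) < 0:
            raise ValueError("counts and lengths must be >= 0")
        for frac in (self.prop_signal, self.enrichment, self.prop_signal_deg):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1], got {frac}")
        if not 0.0 < self.dpsi_effect < 1.0:
            raise ValueError("dpsi_effect must lie in (0, 1)")


def _rng(rng_or_seed: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[dict[str, int], list[GeneModel]]:
    """Place non-overlapping multi-exon genes on both strands of each chromosome."""
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    chroms = list(sizes)
    genes: list[GeneModel] = []
    if config.n_genes == 0 or config.n_chrom == 0:
        return sizes, genes

    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1

    gene_no = 0
    for chrom, g in zip(chroms, per_chrom):
        # draw gene structures first so total span is known before placement
        structures = []
        for _ in range(g):
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
            in_lens = rng.integers(
                config.intron_length[0], config.intron_length[1] + 1, size=max(0, n_ex - 1)
            )
            structures.append((ex_lens, in_lens))
        spans = [int(e.sum() + i_.sum()) for e, i_ in structures]
        free = sizes[chrom] - sum(spans)
        if free < g:
            raise ValueError(
                f"{chrom}: {g} genes spanning {sum(spans)} bp do not fit in "
                f"{sizes[chrom]} bp; increase chrom_length or reduce n_genes"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=g))
        pos = 0
        for k, (ex_lens, in_lens) in enumerate(structures):
            start = int(cuts[k]) + sum(spans[:k])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for j, el in enumerate(ex_lens):
                exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
                pos += int(el)
                if j < len(in_lens):
                    pos += int(in_lens[j])
            gene_no += 1
            genes.append(GeneModel(f"gene{gene_no:04d}", chrom, strand, tuple(exons)))
    return sizes, genes


def _event_geometry(
    gene: GeneModel, event_type: str, rng: np.random.Generator
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]] | None:
    ex = gene.exons
    n = len(ex)
    if event_type == "SE":
        if n < 3:
            return None
        i = int(rng.integers(1, n - 1))
        return (ex[i],), (ex[i - 1], ex[i + 1])
    if event_type == "RI":
        if n < 2:
            return None
        i = int(rng.integers(0, n - 1))
        intron = GenomicInterval(gene.chrom, ex[i].end, ex[i + 1].start, gene.strand)
        return (intron,), (ex[i], ex[i + 1])
    if event_type == "MXE":
        if n < 4:
            return None
        i = int(rng.integers(1, n - 2))
        return (ex[i], ex[i + 1]), (ex[i - 1], ex[i + 2])
    if event_type in ("A5SS", "A3SS"):
        if n < 2:
            return None
        i = int(rng.integers(0, n - 1))
        gap = ex[i + 1].start - ex[i].end
        if gap < 20:
            return None
        ext = int(rng.integers(10, gap // 2 + 1))
        if event_type == "A5SS":
            long_exon = GenomicInterval(gene.chrom, ex[i].start, ex[i].end + ext, gene.strand)
            return (long_exon,), (ex[i + 1],)
        long_exon = GenomicInterval(gene.chrom, ex[i + 1].start - ext, ex[i + 1].end, gene.strand)
        return (long_exon,), (ex[i],)
    raise ValueError(f"unknown event type {event_type!r}")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_events(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    contrasts: Sequence[str],
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, list[SpliceEvent]], dict]:
    """rMATS-style events per contrast with logit-normal replicate PSI noise.

    Group 2 is the shared reference; in each contrast a ``prop_signal``
    fraction of events has its group-1 mean shifted by +/- ``dpsi_effect``.
    P-values come from a two-sample t-test on logit-PSI replicates; FDR is
    Benjamini-Hochberg within each (contrast, event type) table. Truth
    labels record which event ids are signal in which contrast.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)

    # master geometry shared across contrasts
    master: list[tuple[str, str, tuple, tuple, GeneModel, float]] = []
    for etype in EVENT_TYPES:
        want = config.n_events.get(etype, 0)
        made = 0
        attempts = 0
        while made < want and attempts < want * 50 + 100:
            attempts += 1
            gene = genes[int(rng.integers(0, len(genes)))]
            geom = _event_geometry(gene, etype, rng)
            if geom is None:
                continue
            targets, flanks = geom
            psi0 = float(rng.uniform(0.1, 0.9))
            made += 1
            master.append((f"{etype}_{made}", etype, targets, flanks, gene, psi0))
        if made < want:
            raise ValueError(
                f"could only build {made}/{want} {etype} events; "
                "gene models too small for the requested geometry"
            )

    out: dict[str, list[SpliceEvent]] = {}
    truth: dict[str, set[str]] = {}
    for contrast in contrasts:
        signal_mask = rng.random(len(master)) < config.prop_signal
        rows = []
        for (event_id, etype, targets, flanks, gene, psi0), is_signal in zip(
            master, signal_mask
        ):
            mean2 = psi0
            if is_signal:
                direction = 1.0 if rng.random() < 0.5 else -1.0
                mean1 = float(np.clip(psi0 + direction * config.dpsi_effect, 0.01, 0.99))
            else:
                mean1 = psi0
            logit1 = _logit(np.full(config.n_replicates, mean1))
            logit2 = _logit(np.full(config.n_replicates, mean2))
            lv1 = logit1 + rng.normal(0, config.psi_noise_sd, config.n_replicates)
            lv2 = logit2 + rng.normal(0, config.psi_noise_sd, config.n_replicates)
            psi1 = np.clip(_expit(lv1), 0.0, 1.0)
            psi2 = np.clip(_expit(lv2), 0.0, 1.0)
            t = stats.ttest_ind(lv1, lv2)
            p = float(t.pvalue) if math.isfinite(t.pvalue) else 1.0
            rows.append(
                (event_id, etype, targets, flanks, gene, psi1, psi2, p, bool(is_signal))
            )
        # BH within each event-type table, as a per-type rMATS run would
        events: list[SpliceEvent] = []
        truth[contrast] = set()
        for etype in EVENT_TYPES:
            type_rows = [r for r in rows if r[1] == etype]
            if not type_rows:
                continue
            pvals = [r[7] for r in type_rows]
            fdrs = multipletests(pvals, method="fdr_bh")[1]
            for r, fdr in zip(type_rows, fdrs):
                event_id, _, targets, flanks, gene, psi1, psi2, p, is_signal = r
                m1, m2 = float(psi1.mean()), float(psi2.mean())
                events.append(
                    SpliceEvent(
                        event_id=event_id,
                        event_type=etype,
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        target_coords=targets,
                        flank_coords=flanks,
                        psi_group1=m1,
                        psi_group2=m2,
                        delta_psi=m1 - m2,
                        p_value=p,
                        fdr=float(fdr),
                        inc_levels1=tuple(round(float(v), 6) for v in psi1),
                        inc_levels2=tuple(round(float(v), 6) for v in psi2),
                    )
                )
                if is_signal:
                    truth[contrast].add(event_id)
        out[contrast] = events
    return out, {"signal_events": {c: sorted(s) for c, s in truth.items()}}


def _feature_capacity(
    space: FeatureSpace, length: int
) -> tuple[list[GenomicInterval], np.ndarray]:
    ivs = space.all_intervals("exonic") + space.all_intervals("intronic")
    caps = np.asarray([max(0, iv.length - length + 1) for iv in ivs], dtype=np.float64)
    return ivs, caps


def _place_in(iv: GenomicInterval, length: int, rng: np.random.Generator) -> GenomicInterval:
    if iv.length >= length:
        start = int(rng.integers(iv.start, iv.end - length + 1))
    else:  # region shorter than the site: anchor at region start
        start = iv.start
    return GenomicInterval(iv.chrom, start, start + length, iv.strand)


def simulate_clip(
    space: FeatureSpace,
    target_regions: Sequence[GenomicInterval],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[ClipReplicate]:
    """Replicated CLIP interval sets with a planted fraction of sites in
    ``target_regions`` and the rest uniform over the exon/intron space.

    Each replicate carries the common site set with bounded start jitter
    plus replicate-private noise sites; scores are uniform integers over
    ``score_range`` so consensus score filters bite on a known fraction.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    if config.enrichment > 0 and not target_regions:
        raise ValueError("enrichment > 0 requires a non-empty target region set")

    def draw_site() -> GenomicInterval:
        length = int(rng.integers(config.site_length[0], config.site_length[1] + 1))
        if config.enrichment > 0 and rng.random() < config.enrichment:
            region = target_regions[int(rng.integers(0, len(target_regions)))]
            return _place_in(region, length, rng)
        ivs, caps = _feature_capacity(space, length)
        total = caps.sum()
        if total <= 0:
            raise ValueError("feature space has no interval able to contain a site")
        k = int(rng.choice(len(ivs), p=caps / total))
        return _place_in(ivs[k], length, rng)

    common = [draw_site() for _ in range(config.n_sites)]
    scores = rng.integers(config.score_range[0], config.score_range[1] + 1, size=config.n_sites)

    replicates: list[ClipReplicate] = []
    for r in range(config.n_clip_replicates):
        sites: list[GenomicInterval] = []
        for site, score in zip(common, scores):
            jitter = int(rng.integers(-config.replicate_jitter, config.replicate_jitter + 1)) \
                if config.replicate_jitter > 0 else 0
            start = max(0, site.start + jitter)
            sites.append(
                GenomicInterval(site.chrom, start, start + site.length, site.strand,
                                score=float(score))
            )
        for _ in range(config.noise_sites_per_replicate):
            noise = draw_site()
            score = float(rng.integers(config.score_range[0], config.score_range[1] + 1))
            sites.append(GenomicInterval(noise.chrom, noise.start, noise.end, noise.strand,
                                         score=score))
        replicates.append(ClipReplicate(f"rep{r + 1}", sites))
    return replicates


def simulate_deg_table(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[DEGRecord], dict]:
    """DESeq2-style per-gene results: a ``prop_signal_deg`` fraction of genes
    has a true log2FC of +/- ``deg_effect``; observed log2FCs add normal
    noise with standard error ``deg_se`` and p-values are two-sided z-tests,
    BH-adjusted across the table."""
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    n = len(genes)
    signal = rng.random(n) < config.prop_signal_deg
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    true_lfc = np.where(signal, direction * config.deg_effect, 0.0)
    obs_lfc = true_lfc + rng.normal(0, config.deg_se, n)
    z = obs_lfc / config.deg_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1] if n else np.array([])
    records = [
        DEGRecord(genes[i].gene_id, float(obs_lfc[i]), float(p[i]), float(padj[i]))
        for i in range(n)
    ]
    truth = {"signal_genes": sorted(genes[i].gene_id for i in range(n) if signal[i])}
    return records, truth


def simulate_ct(
    config: SimulationConfig,
    true_ratio: float,
    base_ct: float = 20.0,
    sample_id: str = "sample",
    rng: np.random.Generator | int | None = None,
) -> list[CtRecord]:
    """Ct table for one sample where the noiseless inclusion/exclusion ratio
    equals ``true_ratio``; each well gets N(0, ct_noise_sd) noise."""
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    exclusion_ct = base_ct + 4.0
    inclusion_ct = exclusion_ct - math.log2(true_ratio)
    records: list[CtRecord] = []
    for bio in range(1, config.ct_bio_reps + 1):
        for target, clean in (
            ("GAPDH", base_ct),
            ("inclusion", inclusion_ct),
            ("exclusion", exclusion_ct),
        ):
            for tech in range(1, config.ct_tech_reps + 1):
                ct = clean + float(rng.normal(0, config.ct_noise_sd))
                records.append(CtRecord(sample_id, target, bio, tech, ct))
    return records
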