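# spliceclip

Analysis toolkit linking splicing-factor binding sites (CLIP-seq intervals)
to differential alternative-splicing events, built around a strand- and
feature-type-constrained permutation test with Monte Carlo p-values.

What it does:

* **Interval algebra** (`spliceclip.intervals`) — 0-based half-open
  coordinates; merge (book-ended intervals merge), intersect, subtract,
  flank expansion with chromosome clipping, merged exon/intron feature
  spaces with exon precedence, TSS ± 500 bp promoter-window classification.
* **CLIP replicate consensus** (`spliceclip.clip`) — three dataset-specific
  recipes: PAR-CLIP clusters (ReadCount ≥ 40 filter, cross-replicate
  intersection), HITS-CLIP crosslink sites (merge-then-intersect) and
  FLASH-CLIP (merge summing PCR-duplicate scores, score ≥ 10 filter).
* **Splice events** (`spliceclip.events`) — rMATS-style table parsing for
  SE/RI/MXE/A5SS/A3SS, strict FDR/|ΔΨ| significance filters, splicing-
  associated region extraction (target exon/intron plus flanking exons,
  ± 200 bp expansion), observed site/event overlap statistics and ΔΨ
  event × contrast matrices.
* **Permutation enrichment** (`spliceclip.enrichment`) — sites classified
  exonic/intronic (ambiguous sites randomly assigned preserving the
  observed distribution), then re-placed uniformly under four constraints:
  same length, chromosome, strand and feature context, never overlapping
  the original coordinates. 500 iterations by default; Monte Carlo
  p = (1 + #{null ≥ observed}) / (N + 1).
* **Set logic** (`spliceclip.sets`) — DEG filtering (padj < 0.05,
  |log2FC| > 0.58), Venn partitions, uniquely-regulated (co-dependent)
  sets, DEG/AS overlap percentages.
* **qPCR statistics** (`spliceclip.qpcr`) — ΔCt relative expression, the
  exon inclusion/exclusion ratio 2^(ΔCt_inc − ΔCt_exc), ChIP/RIP percent
  of input, t-test / ANOVA + Sidak group comparisons.
* **Synthetic data** (`spliceclip.simulate`) — toy genomes, rMATS-like
  tables with logit-normal PSI noise and known truth labels, replicated
  CLIP files with controllable planted enrichment, DEG and Ct tables.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(per-base interval oracles, hand-computed consensus boundaries, shuffle
uniformity chi-square, null calibration over 200 synthetic datasets,
planted-enrichment power, determinism). The full suite takes a few minutes
on one CPU; most of that is the calibration and power checks.

## Command line

```sh
# end-to-end synthetic pipeline (writes manifest + all stage outputs)
spliceclip run --config config.yaml --seed 1 --out-dir out/

# consensus from replicate BED files
spliceclip clip --recipe parclip --min-readcount 40 --out consensus.bed rep1.bed rep2.bed

# filter events / extract expanded regions / observed overlap
spliceclip events filter SE.MATS.JC.txt RI.MATS.JC.txt
spliceclip events overlap --sites consensus.bed --chrom-sizes chrom.sizes SE.MATS.JC.txt

# permutation enrichment
spliceclip enrich --events SE.MATS.JC.txt --sites consensus.bed \
    --genes genes.exons.tsv --chrom-sizes chrom.sizes \
    --n-iter 500 --seed 1 --out enrichment.json

# DEG/AS set logic and qPCR statistics
spliceclip sets overlap --deg deg.tsv --events SE.MATS.JC.txt
spliceclip qpcr ratio ct.tsv
```

Config files are YAML; see `spliceclip.pipeline.DEFAULT_CONFIG` for keys.
All stochastic outputs embed their seed, and a rerun with the same config
and seed is byte-identical.

## File formats

* BED3–6 (tab-separated, `#`/`track` comments skipped) for sites and peaks.
* Two-column chrom-sizes TSV.
* Minimal exon table for gene models: `gene_id  chrom  strand  exon_start  exon_end`.
* rMATS junction-count dialect per event type (`SE.MATS.JC.txt` layout,
  0-based starts, comma-separated `IncLevel` lists with `NA`).
* DESeq2-style DEG tables (`gene_id  log2FoldChange  pvalue  padj`).
* Ct tables: `sample_id  target  bio_rep  tech_rep  ct`.
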