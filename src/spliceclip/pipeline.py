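"""End-to-end pipeline driver: simulate -> consensus -> filter -> enrich ->
classify, with a run manifest recording seeds, checksums and timings."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__, clip, enrichment, events, io, sets, simulate
from .intervals import build_feature_space, expand, merge

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "contrasts": ["treated_vs_ref", "ko_vs_ref"],
    "codependent_target": "treated_vs_ref",
    "clip_recipe": "parclip",
    "min_read_count": 40,
    "min_score": 10,
    "max_fdr": 0.05,
    "min_abs_dpsi": 0.0,
    "flank": 200,
    "n_iter": 100,
    "stat": "sites",
    "simulation": {},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the full synthetic pipeline and write all stage outputs.

    Returns the run manifest (also written to ``manifest.json``). The same
    config and seed always reproduce byte-identical outputs.
    """
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    contrasts = list(cfg["contrasts"])
    if cfg["codependent_target"] not in contrasts:
        raise ValueError(
            f"unknown codependent target {cfg['codependent_target']!r}; "
            f"contrasts are {contrasts}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.SimulationConfig(**cfg.get("simulation", {}))
    sim_cfg.seed = seed

    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    master = np.random.SeedSequence(seed)
    sub = master.spawn(4)

    t0 = time.perf_counter()
    sizes, genes = simulate.simulate_genome(sim_cfg, np.random.default_rng(sub[0]))
    space = build_feature_space(genes)
    io.write_chrom_sizes(out / "chrom.sizes", sizes)
    io.write_exon_table(out / "genes.exons.tsv", genes)
    outputs["chrom_sizes"] = "chrom.sizes"
    outputs["gene_models"] = "genes.exons.tsv"
    timings["genome"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    events_by_contrast, truth = simulate.simulate_events(
        genes, sim_cfg, contrasts, np.random.default_rng(sub[1])
    )
    for contrast, evs in events_by_contrast.items():
        for etype in events.EVENT_TYPES:
            of_type = [e for e in evs if e.event_type == etype]
            path = out / f"{contrast}.{etype}.MATS.JC.txt"
            events.write_rmats_table(path, of_type, etype)
            outputs[f"rmats/{contrast}/{etype}"] = path.name
    timings["events"] = time.perf_counter() - t0

    # significant events of the first contrast drive the enrichment stage
    primary = contrasts[0]
    significant = events.filter_events(
        events_by_contrast[primary], max_fdr=cfg["max_fdr"], min_abs_dpsi=cfg["min_abs_dpsi"]
    )
    target_regions = merge(
        [
            expand(iv, sizes, cfg["flank"])
            for ev in significant
            for iv in events.event_regions(ev)
        ]
    )

    t0 = time.perf_counter()
    replicates = simulate.simulate_clip(
        space, target_regions, sim_cfg, np.random.default_rng(sub[2])
    )
    for rep in replicates:
        path = out / f"clip.{rep.replicate_id}.bed"
        io.write_bed(path, rep.sites)
        outputs[f"clip/{rep.replicate_id}"] = path.name
    recipe = cfg["clip_recipe"]
    if recipe == "parclip":
        consensus = clip.consensus_parclip(replicates, min_read_count=cfg["min_read_count"])
    elif recipe == "hitsclip":
        consensus = clip.consensus_hitsclip(replicates)
    elif recipe == "flashclip":
        consensus = clip.consensus_flashclip(replicates, min_score=cfg["min_score"])
    else:
        raise ValueError(f"unknown CLIP recipe {recipe!r}")
    io.write_bed(out / "consensus.bed", consensus)
    outputs["consensus"] = "consensus.bed"
    timings["clip"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = enrichment.permutation_enrichment(
        significant,
        consensus,
        space,
        sizes,
        n_iter=cfg["n_iter"],
        flank=cfg["flank"],
        seed=seed,
        stat=cfg["stat"],
    )
    (out / "enrichment.json").write_text(result.to_json() + "\n")
    outputs["enrichment"] = "enrichment.json"
    timings["enrichment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    deg_records, deg_truth = simulate.simulate_deg_table(
        genes, sim_cfg, np.random.default_rng(sub[3])
    )
    sets.write_deg_table(out / "deg.tsv", deg_records)
    outputs["deg"] = "deg.tsv"

    event_sets = {
        contrast: {
            events.event_key(e)
            for e in events.filter_events(evs, max_fdr=cfg["max_fdr"])
        }
        for contrast, evs in events_by_contrast.items()
    }
    venn = sets.venn_partition(event_sets)
    codep = sets.codependent_set(event_sets, cfg["codependent_target"])
    deg_genes = sets.filter_degs(deg_records)
    as_genes = sets.as_gene_set(
        events.filter_events(events_by_contrast[primary], max_fdr=cfg["max_fdr"])
    )
    overlap = sets.deg_as_overlap(deg_genes, as_genes)
    sets_summary = {
        "venn_counts": {
            "+".join(sorted(sig)): len(members) for sig, members in sorted(
                venn.items(), key=lambda kv: sorted(kv[0])
            )
        },
        "codependent_target": cfg["codependent_target"],
        "n_codependent": len(codep),
        "n_deg": len(deg_genes),
        "n_as_genes": len(as_genes),
        "pct_non_overlapping": overlap["pct_non_overlapping"],
        "pct_both": overlap["pct_both"],
    }
    (out / "sets.json").write_text(json.dumps(sets_summary, sort_keys=True, indent=2) + "\n")
    outputs["sets"] = "sets.json"
    (out / "truth.json").write_text(
        json.dumps({**truth, **deg_truth}, sort_keys=True, indent=2) + "\n"
    )
    outputs["truth"] = "truth.json"
    timings["sets"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "simulation_config": asdict(sim_cfg),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "outputs": outputs,
        "checksums": {name: _sha256(out / rel) for name, rel in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
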