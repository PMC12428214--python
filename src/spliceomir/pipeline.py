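"""End-to-end pipeline: generate -> filter -> profile -> scan -> express -> concord.

A run is driven by a structured config (YAML or dict) that either points
at existing input files or carries a ``generate`` block for the synthetic
generator.  A single master seed fans out to stable per-stage seeds, so
stages can be rerun independently and byte-identically.  Every output
file is listed in a manifest with its SHA-256 digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import pandas as pd
import yaml

from . import annotation_io as aio
from . import expression_stats as xs
from . import junction_scan as jscan
from . import segmental_profiler as segp
from . import synthetic_data as synth
from . import trend_concordance as tc

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "outdir", "generate", "inputs", "margin_nt", "border_overhang",
    "min_len", "detect_threshold", "fc_threshold", "pseudo", "upstream",
    "downstream", "allow_gu", "exon_mode", "conflict_share", "diseases",
    "blacklist",
}

_DEFAULTS = dict(
    margin_nt=25, border_overhang=3, min_len=17, detect_threshold=30.0,
    fc_threshold=5.0, pseudo=1.0, upstream=6, downstream=16, allow_gu=False,
    exon_mode=False, conflict_share=0.10,
    diseases=list(synth.DISEASES), blacklist=list(xs.DEFAULT_BLACKLIST),
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived by hashing the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def load_config(source) -> dict:
    """Load and validate a run config from a YAML path or a dict."""
    if isinstance(source, (str, pathlib.Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config requires a seed")
    if "outdir" not in cfg:
        raise ValueError("config requires an outdir")
    if "generate" not in cfg:
        inputs = cfg.get("inputs") or {}
        required = ("genome", "transcripts", "mirnas", "reads", "counts", "trends")
        missing = [k for k in required if k not in inputs]
        if missing:
            raise ValueError(
                f"no generate block and missing input paths: {missing}"
            )
        for k in required:
            if not pathlib.Path(inputs[k]).exists():
                raise ValueError(f"input file for {k!r} not found: {inputs[k]}")
    merged = dict(_DEFAULTS)
    merged.update(cfg)
    for knob in ("margin_nt", "border_overhang", "min_len"):
        if merged[knob] < 0:
            raise ValueError(f"{knob} must be >= 0")
    for knob in ("detect_threshold", "fc_threshold"):
        if merged[knob] <= 0:
            raise ValueError(f"{knob} must be > 0")
    return merged


def _digest(path) -> str:
    return hashlib.sha256(pathlib.Path(path).read_bytes()).hexdigest()


def run(config) -> dict:
    """Execute all stages; returns the manifest (paths, digests, summary)."""
    cfg = load_config(config)
    outdir = pathlib.Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    outputs = {}
    summary = {"seed": seed}

    # --- stage: generate or load -----------------------------------------
    if "generate" in cfg:
        gen = dict(cfg["generate"] or {})
        gen.setdefault("seed", stage_seed(seed, "generate"))
        sim_cfg = synth.SimulationConfig(**gen)
        gendir = outdir / "generated"
        truth, gen_paths = synth.write_synthetic_dataset(gendir, sim_cfg)
        inputs = gen_paths
        summary["generate"] = {"n_mirnas": sim_cfg.n_mirnas,
                               "n_reads": sim_cfg.n_reads,
                               "seed": sim_cfg.seed}
        outputs.update({f"generated_{k}": v for k, v in gen_paths.items()})
    else:
        inputs = cfg["inputs"]

    genomes = aio.read_genome(inputs["genome"])
    transcripts = aio.read_transcripts(inputs["transcripts"])
    loci = aio.read_mirna_loci(inputs["mirnas"])
    reads = aio.read_alignments(inputs["reads"],
                                "sam" if str(inputs["reads"]).endswith(".sam") else "bed")
    matrix = aio.read_counts_tsv(inputs["counts"])
    trend_db = aio.read_trend_table(inputs["trends"])
    contig_lengths = {cid: len(g) for cid, g in genomes.items()}

    # --- stage: filter ----------------------------------------------------
    kept = xs.filter_reads(list(reads), cfg["min_len"])
    summary["filter"] = {"reads_in": len(reads), "reads_kept": len(kept)}

    # --- stage: profile ---------------------------------------------------
    by_locus = segp.assign_reads_to_loci(kept, loci, cfg["margin_nt"], contig_lengths)
    prof = segp.profile(by_locus, loci, cfg["margin_nt"], cfg["border_overhang"],
                        contig_lengths)
    prof_path = outdir / "segment_profile.tsv"
    tbl = prof.per_mirna_class.copy()
    tbl.index.name = "mirna_id"
    tbl.to_csv(prof_path, sep="\t")
    venn_path = outdir / "segment_venn.tsv"
    named = {c: prof.class_sets[c] for c in prof.class_sets}
    segp.venn_table(segp.venn_partition(named)).to_csv(venn_path, sep="\t", index=False)
    outputs["segment_profile"] = str(prof_path)
    outputs["segment_venn"] = str(venn_path)
    summary["profile"] = {
        "n_classified": prof.n_reads, "references": prof.references,
        "unique_items": prof.unique_items,
        "class_read_totals": prof.class_read_totals,
    }

    # --- stage: scan ------------------------------------------------------
    result = jscan.scan(loci, transcripts, genomes, cfg["upstream"],
                        cfg["downstream"], cfg["allow_gu"],
                        exon_mode=cfg["exon_mode"])
    scan_path = outdir / "junction_scan.tsv"
    jscan.scan_report(result).to_csv(scan_path, sep="\t", index=False)
    outputs["junction_scan"] = str(scan_path)
    full_hits = [r for r in result.junction_hits if r.full_complement]
    summary["scan"] = {
        "n_candidates": len(result.junction_hits),
        "n_full_complement": len(full_hits),
        "full_complement": [
            dict(mirna_id=r.mirna_id, arm=r.arm, transcript_id=r.transcript_id,
                 intron_index=r.junction.intron_index)
            for r in full_hits
        ],
        "n_exon_hits": len(result.exon_hits),
    }

    # --- stage: express ---------------------------------------------------
    expr = xs.summarize_expression(
        matrix, cfg["detect_threshold"], cfg["fc_threshold"], cfg["pseudo"],
        tuple(cfg["blacklist"]),
    )
    cpm_path = outdir / "cpm.tsv"
    aio.write_counts_tsv(expr.cpm, cpm_path)
    pooled_path = outdir / "pooled_cpm.tsv"
    pooled = expr.pooled_cpm.sort_index()
    pooled.index.name = "mirna_id"
    pooled.to_csv(pooled_path, sep="\t")
    det_venn_path = outdir / "detection_venn.tsv"
    segp.venn_table(expr.venn_sections).to_csv(det_venn_path, sep="\t", index=False)
    outputs.update(cpm=str(cpm_path), pooled_cpm=str(pooled_path),
                   detection_venn=str(det_venn_path))
    dem_paths = {}
    for (a, b), table in expr.dem_tables.items():
        p = outdir / f"dem_{a}_vs_{b}.tsv"
        t = table.sort_index()
        t.index.name = "mirna_id"
        t.to_csv(p, sep="\t")
        dem_paths[f"{a}_vs_{b}"] = str(p)
    outputs.update({f"dem_{k}": v for k, v in dem_paths.items()})
    summary["express"] = {
        "detected": {line: len(s) for line, s in expr.detection.items()},
        "n_dem": {f"{a}_vs_{b}": int(t["dem"].sum())
                  for (a, b), t in expr.dem_tables.items()},
    }

    # --- stage: concord ---------------------------------------------------
    lines = expr.cpm.cell_lines
    reference = lines[0]
    concord_summaries = {}
    for line in lines[1:]:
        # DEM direction of each cancer-analog line relative to the reference
        table = xs.fold_change_dem(expr.pooled_norm, (line, reference),
                                   cfg["fc_threshold"], cfg["pseudo"])
        calls, csum = tc.classify(table, trend_db, cfg["diseases"],
                                  cfg["conflict_share"])
        p = outdir / f"concordance_{line}_vs_{reference}.tsv"
        tc.calls_table(calls).to_csv(p, sep="\t", index=False)
        outputs[f"concordance_{line}_vs_{reference}"] = str(p)
        concord_summaries[f"{line}_vs_{reference}"] = csum
    summary["concord"] = concord_summaries

    manifest = {
        "outputs": {k: {"path": v, "sha256": _digest(v)} for k, v in sorted(outputs.items())},
        "summary": summary,
        "config": {k: v for k, v in cfg.items()},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("run complete: %d outputs, manifest at %s", len(outputs), manifest_path)
    return manifest
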