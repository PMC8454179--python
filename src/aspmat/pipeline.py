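"""End-to-end pipeline runner: stats → GC scan → centromeres → MAT locus.

Configuration is a versioned YAML/dict schema with one section per stage;
unknown keys are rejected.  Every run writes per-stage TSV/BED files, one
JSON summary, and a MANIFEST with input checksums and stage completion
state, so partial failures leave an auditable trail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import yaml

from . import centromere_scan, gc_landscape, genome_io, locus_compare, mat_locus
from .marker_align import MarkerSet

log = logging.getLogger(__name__)

CONFIG_VERSION = 1

DEFAULT_CONFIG: dict = {
    "version": CONFIG_VERSION,
    "inputs": {"fasta": None, "gff": None, "markers": None, "locus_b": None},
    "output_dir": "aspmat_out",
    "seed": 0,
    "verbosity": "info",
    "gc": {"window": 25, "step": None, "bin": 10_000},
    "centromere": {
        "gc_threshold": 30.0,
        "min_len": 80_000,
        "merge_gap": 2_000,
        "max_small_orfs": 1,
        "small_orf_max_len": 300,
    },
    "mat": {"min_score_fraction": 0.5, "max_span": 100_000},
    "compare": {"motif": "TTACACT", "chain_gap": 2_000},
}


class ConfigError(ValueError):
    pass


def _merge_validate(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_validate(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override dict."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
        cfg = _merge_validate(cfg, file_cfg)
    if overrides:
        cfg = _merge_validate(cfg, overrides)
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run the chained analyses; returns the summary dict (also written to disk).

    Stages degrade gracefully: without a GFF the centromere calls are
    GC-only; without a marker panel the MAT stage is skipped; with a
    second locus FASTA the pairwise comparison runs too.
    """
    cfg = _merge_validate(DEFAULT_CONFIG, config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "inputs": {}, "stages": {}}
    fasta = cfg["inputs"]["fasta"]
    if not fasta:
        raise ConfigError("inputs.fasta is required")
    for key, p in cfg["inputs"].items():
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    summary: dict = {}
    try:
        genome = genome_io.read_fasta(fasta)
        stats = genome_io.assembly_stats(genome)
        summary["stats"] = dataclasses.asdict(stats)
        genome_io.write_tsv_report(
            __import__("pandas").DataFrame([dataclasses.asdict(stats)]), outdir / "stats.tsv"
        )
        manifest["stages"]["stats"] = "completed"

        gc_cfg = cfg["gc"]
        rows = []
        for contig in genome:
            if contig.length < gc_cfg["window"]:
                continue
            prof = gc_landscape.windowed_gc(
                contig.seq, window=gc_cfg["window"], step=gc_cfg["step"], contig_id=contig.id
            )
            rows.append(gc_landscape.summarize_bins(prof, gc_cfg["bin"]).assign(contig=contig.id))
        if rows:
            import pandas as pd

            genome_io.write_tsv_report(pd.concat(rows, ignore_index=True), outdir / "gc_bins.tsv")
        manifest["stages"]["gcscan"] = "completed"

        gff = cfg["inputs"]["gff"]
        annotation = genome_io.read_gff3(gff) if gff else None
        cen_params = centromere_scan.CentromereParams(**cfg["centromere"])
        candidates = centromere_scan.scan_centromeres(genome, annotation, cen_params)
        bed, report = centromere_scan.centromere_report(candidates)
        genome_io.write_bed(bed, outdir / "centromeres.bed")
        genome_io.write_tsv_report(report, outdir / "centromeres.tsv")
        summary["centromeres"] = {
            "n_candidates": len(candidates),
            "gc_only": annotation is None,
            "candidates": report.to_dict(orient="records"),
        }
        manifest["stages"]["centromeres"] = "completed"

        markers_path = cfg["inputs"]["markers"]
        if markers_path:
            markers = MarkerSet.from_fasta(markers_path)
            params = mat_locus.MatParams(**cfg["mat"])
            call = mat_locus.call_mat_locus(genome, markers, params=params)
            summary["mat_locus"] = call.to_dict()
            genome_io.write_json_report(call.to_dict(), outdir / "mat_locus.json")
            manifest["stages"]["matlocus"] = "completed"

            locus_b = cfg["inputs"]["locus_b"]
            if locus_b:
                other = genome_io.read_fasta(locus_b)
                cmp_cfg = cfg["compare"]
                params_c = locus_compare.CompareParams(chain_gap=cmp_cfg["chain_gap"])
                seq_a = genome[0].seq
                seq_b = other[0].seq
                blocks = locus_compare.homology_blocks(seq_a, seq_b, params_c)
                bps = locus_compare.find_breakpoints(blocks, (len(seq_a), len(seq_b)), params_c)
                sites = locus_compare.motif_scan(seq_a, cmp_cfg["motif"], locus="A")
                sites += locus_compare.motif_scan(seq_b, cmp_cfg["motif"], locus="B")
                sites = locus_compare.annotate_motif_breakpoint_proximity(sites, bps)
                summary["locus_compare"] = {
                    "n_blocks": len(blocks),
                    "n_breakpoints": len(bps),
                    "n_motif_sites": len(sites),
                }
                manifest["stages"]["compare-loci"] = "completed"
    finally:
        genome_io.write_json_report(manifest, outdir / "MANIFEST.json")
    genome_io.write_json_report(summary, outdir / "summary.json")
    return summary
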