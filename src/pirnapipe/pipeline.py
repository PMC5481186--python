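"""End-to-end orchestration: simulate libraries, process reads, analyze.

``run_simulate`` writes, per configured library, a FASTQ plus the shared
reporter FASTA, sites BED and truth TSV, together with a manifest recording
the seed and file map.  ``run_analyze`` reads those files back and executes
trim -> length filter -> align -> end-distance profiles -> product calls ->
relative ratios -> ping-pong, emitting a JSON report and TSV tables.  With
a fixed seed the whole round trip is deterministic.

Libraries stay in separate FASTQ files (the manifest maps file to library):
inline 3' barcodes are unrecoverable from maximum-length reads, so pooled
demultiplexing would silently drop the 51-mer intermediates.  The
``demultiplex`` operation remains available for genuinely pooled input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io
from .abundance import length_distribution, modal_length
from .config import RunConfig
from .pingpong import PositionWeights, pingpong_score, weights_from_alignments
from .readproc import Read, align_reads, filter_min_length, trim_adapter
from .simulate import build_reporter, simulate_biogenesis, simulate_library
from .site_products import (
    ClassifyParams,
    classify_all,
    profile_distances,
    relative_ratios,
)

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_analyze"]


def run_simulate(config: RunConfig, outdir: str | Path) -> dict:
    """Generate all synthetic outputs; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.sim.seed)
    reporter = build_reporter(config.sim, rng=rng)
    io.write_fasta({reporter.name: reporter.sequence}, outdir / "reporter.fa")
    io.write_sites_bed(reporter, outdir / "sites.bed")

    manifest = {
        "seed": config.sim.seed,
        "n_sites": len(reporter.sites),
        "reporter_fasta": "reporter.fa",
        "sites_bed": "sites.bed",
        "libraries": {},
    }
    all_truths = []
    for lib in config.libraries:
        params = replace(config.sim, conversion_efficiency=lib.conversion_efficiency)
        fragments, truths = simulate_biogenesis(reporter, params, rng)
        records = simulate_library(fragments, params, lib.tag)
        fq = f"{lib.tag}.fastq"
        io.write_fastq(records, outdir / fq)
        all_truths.extend(
            replace(t, read_id=f"{lib.tag}.{t.read_id}") for t in truths
        )
        manifest["libraries"][lib.tag] = {
            "fastq": fq,
            "genotype": lib.genotype,
            "conversion_efficiency": lib.conversion_efficiency,
            "barcode": config.sim.barcode_map[lib.tag],
            "n_reads": len(records),
        }
        if not records:
            logger.warning("library %s is empty", lib.tag)
    io.write_truth(all_truths, outdir / "truth.tsv")
    manifest["truth_tsv"] = "truth.tsv"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _process_library(reads, barcode, config: RunConfig, reference: str):
    """trim -> filter -> exact align; returns (aligned, unaligned)."""
    adapter = barcode + config.sim.adapter_seq
    trimmed = []
    for r in reads:
        seq = trim_adapter(r.sequence, adapter, config.analysis.trim_min_overlap)
        if seq:
            trimmed.append(Read(r.read_id, seq, r.library_tag))
    kept = filter_min_length(trimmed, config.analysis.min_read_length)
    return align_reads(
        kept, {"reporter": reference}, max_mm=config.analysis.max_mm
    )


def run_analyze(config: RunConfig, simdir: str | Path, outdir: str | Path) -> dict:
    """Run the full analysis on simulated (or compatible) inputs."""
    simdir, outdir = Path(simdir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((simdir / "manifest.json").read_text())
    reference = io.read_fasta(simdir / manifest["reporter_fasta"])
    ref_seq = next(iter(reference.values()))
    sites = io.read_sites_bed(simdir / manifest["sites_bed"])

    ana = config.analysis
    cls_params = ClassifyParams(
        pirna_min=ana.pirna_min,
        pirna_max=ana.pirna_max,
        max_read_length=config.sim.max_read_length,
        byproduct_length=config.sim.byproduct_length,
        trail_window=ana.trail_window,
    )
    # targeting-guide 5' ends: minus-strand, at each site's q coordinate
    guide_weights = PositionWeights(
        "reporter", "-", {s.origin - 1: 1.0 for s in sites}, "five_prime"
    )

    report: dict = {"seed": config.sim.seed, "libraries": {}}
    for tag, meta in manifest["libraries"].items():
        reads = io.read_fastq(simdir / meta["fastq"], tag)
        aligned, unaligned = _process_library(reads, meta["barcode"], config, ref_seq)
        io.write_alignments(aligned, outdir / f"{tag}.alignments.tsv")

        calls = classify_all(aligned, sites, cls_params)
        calls.to_csv(outdir / f"{tag}.calls.tsv", sep="\t", index=False)
        ratios = relative_ratios(calls, rpm_total=len(aligned) or None)

        prof_pirna = profile_distances(aligned, sites, (ana.pirna_min, ana.pirna_max))
        prof_pirna.to_csv(outdir / f"{tag}.profile_pirna.tsv", sep="\t")
        bp_len = config.sim.byproduct_length
        prof_bp = profile_distances(aligned, sites, (bp_len, bp_len))
        prof_bp.to_csv(outdir / f"{tag}.profile_byproduct.tsv", sep="\t")

        pirna_calls = calls[calls["call"].isin(["secondary_piRNA", "trail_piRNA"])]
        pirna_ids = set(pirna_calls["read_id"])
        pirna_aligned = [r for r in aligned if r.read_id in pirna_ids]
        produced = weights_from_alignments(
            pirna_aligned, "+", "five_prime", "reporter"
        )
        pp = pingpong_score(produced, guide_weights, ana.delta_range)

        lengths_all = length_distribution([r.length for r in aligned])
        lengths_all.to_csv(outdir / f"{tag}.lengths.tsv", sep="\t")

        report["libraries"][tag] = {
            "genotype": meta["genotype"],
            "n_reads": len(reads),
            "n_aligned": len(aligned),
            "n_unaligned": len(unaligned),
            "argmax_d5_pirna": _argmax_or_none(prof_pirna, "count_5p"),
            "argmax_d3_byproduct": _argmax_or_none(prof_bp, "count_3p"),
            "pingpong_argmax_delta": pp.argmax_delta,
            "modal_length_pirna": modal_length(list(pirna_calls["length"])),
            "modal_length_byproduct": modal_length(
                list(calls.loc[calls["call"] == "byproduct_16mer", "length"])
            ),
            "modal_length_unaligned": modal_length(
                [len(r.sequence) for r in unaligned]
            ),
            "ratios": {k: _json_safe(v) for k, v in ratios.items()},
        }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def _argmax_or_none(profile, column):
    if profile.empty or profile[column].max() <= 0:
        return None
    return int(profile[column].idxmax())


def _json_safe(v):
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v
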