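"""Run configuration and the end-to-end pipeline driver.

A single JSON config drives the whole chain
simulate -> binmap -> preprocess -> cnprofile -> baf -> compare.
One global seed fans out to per-stage seeds (derived by hashing the stage
name) so any stage can be rerun independently yet deterministically; reruns
with the same config and seed produce byte-identical artifacts. Every run
writes the resolved config and a manifest listing each artifact with its
SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import pandas as pd

from . import _io
from .allele_typing import AllelicStateThresholds, classify_allelic_state, compute_baf
from .cn_profile import single_cell_cn_profile
from .mappability import bin_size_summary, build_variable_bins, compute_unique_positions
from .pcf import SegmentationParams
from .profile_compare import classify_events, concordance, status_track
from .read_preprocess import (
    coverage_stats,
    dedup_alignments,
    map_reads_exact,
    profile_adapter,
    trim_reads,
)
from .synthetic_data import (
    Clone,
    CnEvent,
    ReadSimSpec,
    SimGenomeSpec,
    SnpDepthSpec,
    clone_cn_tracks,
    make_snp_panel,
    simulate_cell_reads,
    simulate_genome,
    simulate_primary_track,
    simulate_snp_counts,
    simulate_tumor_truth,
    write_truth_bed,
)

log = logging.getLogger("scellcn")


@dataclass
class RunConfig:
    """All pipeline tunables, defaulting to the published analysis values."""

    seed: int = 0
    outdir: str = "scellcn_run"
    # genome / truth
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    # reads
    n_reads: int = 60_000
    trim: int = 32
    read_length: int = 69
    duplicate_rate: float = 0.05
    gc_bias_coeff: float = 0.4
    amplification_dispersion: float = 0.15
    # binning
    bin_unique: int = 2_000
    # cn profile
    pseudocount: float = 1.0
    gc_min: float = 0.28
    gamma_seq: float = 25.0
    kmin_seq: int = 1
    loess_span: float = 0.3
    loess_degree: int = 2
    # aCGH mode
    gamma_acgh: float = 60.0
    kmin_acgh: int = 25
    acgh_floor: float = -2.0
    # BAF
    min_depth: int = 8
    n_snp_sites: int = 3_000
    snp_mean_depth: float = 15.0
    # comparison
    min_jaccard: float = 0.5
    subclonal_max_fraction: float = 0.8

    _RANGES = {
        "trim": (0, None),
        "read_length": (1, None),
        "duplicate_rate": (0.0, 1.0),
        "gc_min": (0.0, 1.0),
        "gamma_seq": (0.0, None),
        "gamma_acgh": (0.0, None),
        "kmin_seq": (1, None),
        "kmin_acgh": (1, None),
        "min_depth": (1, None),
        "pseudocount": (0.0, None),
        "bin_unique": (1, None),
        "n_reads": (0, None),
        "chrom_length": (1, None),
        "n_chroms": (1, None),
        "loess_span": (0.0, 1.0),
        "subclonal_max_fraction": (0.0, 1.0),
        "min_jaccard": (0.0, 1.0),
    }


def validate_config(source: str | dict) -> RunConfig:
    """Build a RunConfig from a JSON file path or a dict, aggregating errors.

    Unknown keys and out-of-range values are all reported together in a
    single ``ValueError`` rather than first-fail.
    """
    if isinstance(source, str):
        with open(source) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed JSON in {source}: {exc}") from exc
    else:
        data = dict(source)
    errors = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    cfg_kwargs = {k: v for k, v in data.items() if k in known}
    cfg = RunConfig(**cfg_kwargs)
    for key, (lo, hi) in RunConfig._RANGES.items():
        v = getattr(cfg, key)
        if lo is not None and v < lo:
            errors.append(f"{key}={v} below minimum {lo}")
        if hi is not None and v > hi:
            errors.append(f"{key}={v} above maximum {hi}")
    if errors:
        raise ValueError("; ".join(errors))
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def default_demo_truth(cfg: RunConfig):
    """Two-clone tumor used by the bundled demo run.

    The dominant clone carries a whole-arm-style gain, a focal deletion
    and a cnLOH region; a 30% subclone adds a private focal gain. The
    sequenced cell is the dominant clone.
    """
    L = cfg.chrom_length
    lengths = {f"chr{i+1}": L for i in range(cfg.n_chroms)}
    major = Clone(
        "cloneA",
        0.7,
        [
            CnEvent("chr1", L // 2, L, "A", +1, "arm"),
            CnEvent("chr2", L // 10, L // 10 + L // 8, "B", -1, "focal"),
            CnEvent("chr2", 6 * L // 10, 8 * L // 10, "A", 0, "cnLOH"),
        ],
    )
    minor = Clone(
        "cloneB",
        0.3,
        [
            CnEvent("chr1", L // 2, L, "A", +1, "arm"),
            CnEvent("chr2", 85 * L // 100, 95 * L // 100, "A", +1, "focal"),
        ],
    )
    return lengths, [major, minor]


def run_pipeline(config: RunConfig, until: str | None = None) -> dict:
    """Execute the stages in order; returns the artifact manifest.

    ``until`` stops after the named stage (e.g. ``"simulate"``). Any stage
    failure raises with the stage named; artifacts written before the
    failure are retained.
    """
    out = config.outdir
    _io.ensure_dir(out)
    manifest: dict = {"stages": [], "artifacts": {}}
    resolved = os.path.join(out, "config.json")
    with open(resolved, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    def artifact(name: str, path: str) -> None:
        manifest["artifacts"][name] = {"path": path, "sha256": _checksum(path)}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        gspec = SimGenomeSpec(
            n_chroms=config.n_chroms,
            chrom_length=config.chrom_length,
            seed=stage_seed(config.seed, "genome"),
        )
        genome, _ = simulate_genome(gspec)
        lengths, plan = default_demo_truth(config)
        truth = simulate_tumor_truth(lengths, plan, seed=stage_seed(config.seed, "truth"))
        rspec = ReadSimSpec(
            n_reads=config.n_reads,
            read_length_raw=config.read_length + config.trim,
            duplicate_rate=config.duplicate_rate,
            gc_bias_coeff=config.gc_bias_coeff,
            amplification_dispersion=config.amplification_dispersion,
            seed=stage_seed(config.seed, "reads"),
        )
        reads, true_aln = simulate_cell_reads(genome, truth, "cloneA", rspec)
        # germline heterozygous SNPs: the sites BAF typing is informative at
        panel = make_snp_panel(
            genome, config.n_snp_sites, het_fraction=1.0,
            seed=stage_seed(config.seed, "panel"),
        )
        counts = simulate_snp_counts(
            truth,
            "cloneA",
            panel,
            SnpDepthSpec(
                mean_depth=config.snp_mean_depth, seed=stage_seed(config.seed, "snp")
            ),
        )
        fasta = os.path.join(out, "genome.fa")
        fastq = os.path.join(out, "reads.fq")
        _io.write_fasta(genome, fasta)
        _io.write_fastq(reads, fastq)
        _io.write_sam(
            true_aln, lengths, os.path.join(out, "true_alignments.sam"),
            read_length=config.read_length,
        )
        write_truth_bed(truth, os.path.join(out, "truth.tsv"))
        _io.write_vcf(panel.sites, lengths, os.path.join(out, "panel.vcf"))
        _io.write_table(counts, os.path.join(out, "snp_counts.tsv"))
        for name in ("genome.fa", "reads.fq", "true_alignments.sam", "truth.tsv",
                     "panel.vcf", "snp_counts.tsv"):
            artifact(name, os.path.join(out, name))
        manifest["stages"].append(stage)
        if until == stage:
            return _finish(manifest, out)

        stage = "binmap"
        log.info("stage %s", stage)
        mask = compute_unique_positions(genome, config.read_length)
        bins = build_variable_bins(mask, genome, config.bin_unique)
        mean_w, sd_w = bin_size_summary(bins)
        _io.write_table(bins, os.path.join(out, "bins.bed"))
        artifact("bins.bed", os.path.join(out, "bins.bed"))
        manifest["bin_width_mean"] = mean_w
        manifest["bin_width_sd"] = sd_w
        manifest["stages"].append(stage)

        stage = "preprocess"
        log.info("stage %s", stage)
        raw = _io.read_fastq(fastq)
        prof = profile_adapter(raw)
        trimmed, n_dropped = trim_reads(raw, config.trim)
        aln, counters = map_reads_exact(trimmed, genome)
        aln = dedup_alignments(aln)
        cov = coverage_stats(aln, sum(lengths.values()), config.read_length)
        _io.write_alignment_bed(aln, os.path.join(out, "alignments.bed"),
                                read_length=config.read_length)
        artifact("alignments.bed", os.path.join(out, "alignments.bed"))
        stats = {
            "suggested_trim": prof.suggested_trim,
            "reads_dropped_by_trim": n_dropped,
            **counters,
            "breadth": cov.breadth,
            "depth_genome": cov.depth_genome,
            "depth_covered": cov.depth_covered,
        }
        with open(os.path.join(out, "preprocess_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2)
        artifact("preprocess_stats.json", os.path.join(out, "preprocess_stats.json"))
        manifest["stages"].append(stage)

        stage = "cnprofile"
        log.info("stage %s", stage)
        ref_region = ("chr1", 0, config.chrom_length // 2)
        track, segments, ploidy = single_cell_cn_profile(
            aln, bins, ref_region,
            pseudocount=config.pseudocount, gc_min=config.gc_min,
            gamma=config.gamma_seq, kmin=config.kmin_seq,
            span=config.loess_span, degree=config.loess_degree,
        )
        _io.write_table(track, os.path.join(out, "logr_track.tsv"))
        _io.write_table(segments, os.path.join(out, "cn_segments.tsv"))
        artifact("logr_track.tsv", os.path.join(out, "logr_track.tsv"))
        artifact("cn_segments.tsv", os.path.join(out, "cn_segments.tsv"))
        manifest["psi"] = ploidy.psi
        manifest["stages"].append(stage)

        stage = "baf"
        log.info("stage %s", stage)
        baf = compute_baf(counts, config.min_depth)
        states = classify_allelic_state(baf, segments, AllelicStateThresholds())
        _io.write_table(baf, os.path.join(out, "baf_sites.tsv"))
        _io.write_table(states, os.path.join(out, "allelic_states.tsv"))
        artifact("baf_sites.tsv", os.path.join(out, "baf_sites.tsv"))
        artifact("allelic_states.tsv", os.path.join(out, "allelic_states.tsv"))
        manifest["stages"].append(stage)

        stage = "compare"
        log.info("stage %s", stage)
        dtc_status = status_track(segments)
        primary_cn = clone_cn_tracks(truth, "cloneA").rename(columns={})
        primary_cn["cn_integer"] = primary_cn["cn_a"] + primary_cn["cn_b"]
        report = concordance(dtc_status, status_track(primary_cn))
        events = classify_events(
            segments, truth,
            min_jaccard=config.min_jaccard,
            subclonal_max_fraction=config.subclonal_max_fraction,
        )
        _io.write_table(events, os.path.join(out, "event_comparison.tsv"))
        artifact("event_comparison.tsv", os.path.join(out, "event_comparison.tsv"))
        manifest["concordance"] = report.concordance
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return _finish(manifest, out)


def _finish(manifest: dict, out: str) -> dict:
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
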