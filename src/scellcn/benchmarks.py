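"""Reproducible end-to-end studies exercising the whole pipeline.

Each function builds its own inputs with the synthetic-data module (or from
published summary values, for the coverage worked examples), runs the
pipeline operations under study, and measures the outcome. They are used by
the acceptance script and the test suite; all randomness is controlled by
the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .allele_typing import classify_allelic_state, compute_baf
from .cn_profile import gc_correct, process_acgh_track, single_cell_cn_profile
from .mappability import build_variable_bins, compute_unique_positions
from .pcf import SegmentationParams, pcf_segment, segment_oracle
from .profile_compare import concordance, status_track
from .read_preprocess import (
    CoverageStats,
    coverage_stats,
    dedup_alignments,
    map_reads_exact,
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
    simulate_snp_counts,
    simulate_tumor_truth,
)

#: Published per-cell sequencing summaries: genome-relative depth and breadth.
PUBLISHED_COVERAGE = {
    "DTC003": {"depth_genome": 2.92, "breadth": 0.339},
    "DTC083": {"depth_genome": 2.03, "breadth": 0.387},
}


def coverage_worked_examples() -> dict[str, float]:
    """Depth over covered bases recomputed from depth and breadth summaries."""
    return {
        cell: round(
            CoverageStats.from_depth_breadth(v["depth_genome"], v["breadth"]).depth_covered,
            2,
        )
        for cell, v in PUBLISHED_COVERAGE.items()
    }


def pcf_oracle_agreement(seed: int, n_series: int = 200) -> dict:
    """Exact-DP segmentation versus exhaustive enumeration on random series."""
    rng = np.random.default_rng(seed)
    gammas = [0.5, 5.0, 25.0, 60.0]
    kmins = [1, 2, 3]
    agree = 0
    max_diff = 0.0
    for _ in range(n_series):
        n = int(rng.integers(5, 13))
        y = rng.normal(0, 1, n) + np.repeat(rng.normal(0, 2, 2), [n // 2, n - n // 2])
        params = SegmentationParams(
            gamma=gammas[rng.integers(len(gammas))], kmin=kmins[rng.integers(len(kmins))]
        )
        fit = pcf_segment(y, params)
        ref = segment_oracle(y, params)
        diff = abs(fit.objective - ref.objective)
        max_diff = max(max_diff, diff)
        agree += diff <= 1e-9 and fit.breakpoints == ref.breakpoints
    return {"n_series": n_series, "n_agree": agree, "max_objective_diff": max_diff}


def cn_recovery_study(seed: int) -> dict:
    """One simulated WGA cell, full pipeline, scored against planted truth.

    Toy genome of 2 x 5 Mb (~2020 variable bins of 4950 unique positions,
    ~28 deduplicated reads per bin), diploid baseline with a planted arm
    gain (CN 3), a 500 kb focal deletion (CN 1) and a 1 Mb cnLOH region;
    ploidy anchored on a CN-2 reference region.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_truth, s_reads, s_panel, s_snp = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    )
    spec = SimGenomeSpec(n_chroms=2, chrom_length=5_000_000, seed=s_genome)
    genome, _ = simulate_genome(spec)
    lengths = {c: len(s) for c, s in genome.items()}
    cnloh_region = ("chr2", 3_000_000, 4_000_000)
    plan = [
        Clone(
            "cell",
            1.0,
            [
                CnEvent("chr1", 2_500_000, 5_000_000, "A", +1, "arm"),
                CnEvent("chr2", 900_000, 1_400_000, "B", -1, "focal"),
                CnEvent("chr2", *cnloh_region[1:], "A", 0, "cnLOH"),
            ],
        )
    ]
    truth = simulate_tumor_truth(lengths, plan, seed=s_truth)
    reads, _ = simulate_cell_reads(
        genome, truth, "cell", ReadSimSpec(n_reads=60_000, seed=s_reads)
    )
    trimmed, _ = trim_reads(reads, 32)
    aln, _ = map_reads_exact(trimmed, genome)
    aln = dedup_alignments(aln)
    mask = compute_unique_positions(genome, 69)
    bins = build_variable_bins(mask, genome, 4_950)
    track, segments, ploidy = single_cell_cn_profile(aln, bins, ("chr1", 0, 2_400_000))

    truth_cn = clone_cn_tracks(truth, "cell")
    truth_cn["cn_true"] = truth_cn["cn_a"] + truth_cn["cn_b"]
    correct = total = 0
    for s in segments.itertuples(index=False):
        sub = truth_cn[truth_cn["chrom"] == s.chrom]
        for t in sub.itertuples(index=False):
            ov = max(0, min(s.end, t.end) - max(s.start, t.start))
            total += ov
            if s.cn_integer == t.cn_true:
                correct += ov

    panel = make_snp_panel(genome, 4_000, het_fraction=1.0, seed=s_panel)
    counts = simulate_snp_counts(
        truth, "cell", panel, SnpDepthSpec(mean_depth=15, seed=s_snp)
    )
    baf = compute_baf(counts)
    # allelic state of the planted cnLOH region, with its dosage-called CN
    chrom, start, end = cnloh_region
    over = segments[
        (segments["chrom"] == chrom)
        & (segments["end"] > start)
        & (segments["start"] < end)
    ]
    region_cn = int(round(float(over["cn_integer"].mean()))) if len(over) else 2
    region = pd.DataFrame(
        [{"chrom": chrom, "start": start, "end": end, "cn_integer": region_cn}]
    )
    cnloh_state = classify_allelic_state(baf, region)["state"].iloc[0]
    return {
        "bp_accuracy": correct / total,
        "compared_bp": total,
        "n_bins": len(bins),
        "reads_per_bin": len(aln) / len(bins),
        "psi": ploidy.psi,
        "cnloh_state": cnloh_state,
        "segments": segments,
    }


def gc_debias_study(seed: int, n_bins: int = 2_000) -> dict:
    """Injected log-linear GC bias removed by the loess correction."""
    rng = np.random.default_rng(seed)
    gc = rng.uniform(0.3, 0.6, n_bins)
    logr = 0.8 * (gc - gc.mean()) + rng.normal(0, 0.1, n_bins)
    track = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_bins) * 1_000,
            "end": (np.arange(n_bins) + 1) * 1_000,
            "gc": gc,
            "logr": logr,
        }
    )
    corrected = gc_correct(track)
    return {
        "n_bins": n_bins,
        "abs_spearman_before": float(abs(spearmanr(logr, gc).statistic)),
        "abs_spearman_after": float(abs(spearmanr(corrected["logr"], gc).statistic)),
    }


def mappability_agreement(seed: int, read_length: int = 69) -> dict:
    """Hash-based mask versus a brute-force k-mer dictionary on a small genome."""
    from collections import Counter

    from ._io import revcomp

    spec = SimGenomeSpec(
        n_chroms=2,
        chrom_length=100_000,
        planted_duplications=[
            ("chr1", 20_000, 25_000, "chr2", 60_000),
            ("chr1", 40_000, 42_000, "chr1", 70_000),
        ],
        seed=seed,
    )
    genome, _ = simulate_genome(spec)
    mask = compute_unique_positions(genome, read_length)

    counts: Counter = Counter()
    acgt = set("ACGT")
    for seq in genome.values():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - read_length + 1):
                km = strand_seq[i : i + read_length]
                if set(km) <= acgt:
                    counts[km] += 1
    mismatches = 0
    n_positions = 0
    for chrom, seq in genome.items():
        m = mask.masks[chrom]
        n_positions += len(m)
        for i in range(len(seq) - read_length + 1):
            km = seq[i : i + read_length]
            expected = set(km) <= acgt and counts[km] == 1
            mismatches += expected != bool(m[i])
        mismatches += int(m[len(seq) - read_length + 1 :].sum())
    return {"n_positions": n_positions, "mismatches": mismatches}


def concordance_calibration(seed: int, reps: int = 50) -> dict:
    """Concordance versus constructed DTC-private genome fraction."""
    rng = np.random.default_rng(seed)
    n_windows = 1_000
    width = 10_000
    max_err = 0.0
    fractions = (0.01, 0.1, 0.25)
    for f in fractions:
        for _ in range(reps):
            cns = rng.choice([1, 2, 2, 2, 3], size=n_windows)
            profile = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": np.arange(n_windows) * width,
                    "end": (np.arange(n_windows) + 1) * width,
                    "cn_integer": cns,
                }
            )
            a = status_track(profile)
            k = int(round(f * n_windows))
            flip = rng.choice(n_windows, size=k, replace=False)
            cns_b = cns.copy()
            cns_b[flip] = np.where(cns[flip] == 2, 3, 2)
            b = status_track(profile.assign(cn_integer=cns_b))
            err = abs(concordance(a, b).concordance - (1 - f))
            max_err = max(max_err, err)
    return {"reps_per_fraction": reps, "fractions": fractions, "max_abs_error": max_err}


def acgh_contract_study(seed: int) -> dict:
    """Floor/recentring contract and step recovery in aCGH mode."""
    rng = np.random.default_rng(seed)
    n_per_state = 200
    values = np.concatenate(
        [
            rng.normal(0.0, 0.15, n_per_state),
            rng.normal(1.0, 0.15, n_per_state),
            rng.normal(-1.0, 0.15, n_per_state),
        ]
    )
    values[rng.integers(0, len(values), 3)] = -5.0  # outliers the floor clamps
    probes = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(len(values)) * 1_000 + 500, "logr": values}
    )
    processed, segments = process_acgh_track(probes)
    true_bkp_pos = [n_per_state * 1_000 + 500, 2 * n_per_state * 1_000 + 500]
    offsets = []
    for bp in true_bkp_pos:
        found = segments["start"].iloc[1:].to_numpy()
        offsets.append(int(np.min(np.abs(found - bp))) // 1_000 if len(found) else 999)
    return {
        "n_probes": len(values),
        "min_value": float(processed["logr"].min()),
        "abs_mean": float(abs(processed["logr"].mean())),
        "n_segments": len(segments),
        "max_breakpoint_offset_probes": max(offsets),
    }


def coverage_identity_study(seed: int) -> dict:
    """depth_covered x breadth == depth_genome across random alignment sets."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    n_fixtures = 20
    for _ in range(n_fixtures):
        n = int(rng.integers(1, 500))
        aln = pd.DataFrame(
            {
                "qname": [f"r{i}" for i in range(n)],
                "chrom": rng.choice(["chr1", "chr2"], size=n),
                "start": rng.integers(0, 10_000, size=n),
                "strand": rng.choice(["+", "-"], size=n),
            }
        )
        cov = coverage_stats(aln, genome_length=20_000, read_length=69)
        max_err = max(max_err, abs(cov.depth_covered * cov.breadth - cov.depth_genome))
    return {"n_fixtures": n_fixtures, "max_abs_error": max_err}
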