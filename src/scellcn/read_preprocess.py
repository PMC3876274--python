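"""Adapter trimming, toy exact-match mapping, deduplication, coverage.

WGA adapter sequence contaminates the 5' end of single-cell reads; it is
detected by profiling recurrent bases per read position and removed by
trimming a fixed prefix (32 bases by default, leaving 69-base reads).
Trimmed reads are placed by exact sequence match against the reference on
either strand; reads matching no locus or more than one are discarded, the
latter mirroring the multi-mapper discard of real aligners. PCR duplicates
are collapsed on the (chrom, start, strand) key, and breadth/depth of
coverage are computed from the surviving alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import ALIGNMENT_COLUMNS, encode_sequence, revcomp
from .mappability import _HASH_MULTIPLIERS, _rolling_hashes, _window_valid

_PROFILE_SAMPLE_CAP = 100_000  # reads inspected when profiling the adapter


@dataclass
class AdapterProfile:
    """Per-position base frequencies over read prefixes.

    ``frequencies`` has shape (max_len, 5) over A,C,G,T,other;
    ``suggested_trim`` is the longest prefix over which every position's
    modal base reaches the dominance threshold.
    """

    frequencies: np.ndarray
    suggested_trim: int
    dominance: float


@dataclass
class CoverageStats:
    """Breadth and depth of coverage.

    ``depth_genome`` is mean depth over the whole reference,
    ``depth_covered`` over covered bases only; the identity
    ``depth_covered * breadth = depth_genome`` holds exactly.
    """

    breadth: float
    depth_genome: float
    depth_covered: float

    @classmethod
    def from_depth_breadth(cls, depth_genome: float, breadth: float) -> "CoverageStats":
        """Build from genome-relative depth and breadth (e.g. published values)."""
        if not 0 <= breadth <= 1:
            raise ValueError("breadth must lie in [0,1]")
        depth_covered = depth_genome / breadth if breadth > 0 else 0.0
        return cls(breadth=breadth, depth_genome=depth_genome, depth_covered=depth_covered)


def _sequences(reads: Sequence) -> list[str]:
    if len(reads) and isinstance(reads[0], tuple):
        return [r[1] for r in reads]
    return list(reads)


def profile_adapter(
    reads: Sequence, max_len: int = 50, dominance: float = 0.8
) -> AdapterProfile:
    """Profile recurrent bases at each leading read position.

    Only the first 100k reads are inspected. Raises on empty input. A
    suggested trim equal to ``max_len`` (reads identical over the whole
    profiled range) is degenerate and triggers a warning.
    """
    seqs = _sequences(reads)[:_PROFILE_SAMPLE_CAP]
    if not seqs:
        raise ValueError("cannot profile an empty read set")
    counts = np.zeros((max_len, 5), dtype=np.int64)
    for s in seqs:
        codes = encode_sequence(s[:max_len])
        counts[np.arange(len(codes)), codes] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    modal = freqs.max(axis=1)
    covered = totals[:, 0] > 0
    trim = 0
    while trim < max_len and covered[trim] and modal[trim] >= dominance:
        trim += 1
    if trim == max_len:
        warnings.warn(
            "reads are near-identical over the whole profiled range; "
            "suggested trim equals max_len"
        )
    return AdapterProfile(frequencies=freqs, suggested_trim=trim, dominance=dominance)


def trim_reads(
    reads: Sequence[tuple[str, str, str]], n: int = 32
) -> tuple[list[tuple[str, str, str]], int]:
    """Drop the first ``n`` bases (and qualities) of every read.

    Reads with no sequence left after trimming are dropped; the second
    return value counts them.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    kept = []
    dropped = 0
    for name, seq, qual in reads:
        if len(seq) <= n:
            dropped += 1
            continue
        kept.append((name, seq[n:], qual[n:] if qual else qual))
    return kept, dropped


def map_reads_exact(
    reads: Sequence[tuple[str, str, str]], genome: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Place each read where its sequence (or reverse complement) matches.

    Exact match only: reads matching zero loci are unmapped, reads matching
    more than one locus (over both strands) are discarded as multi-mappers.
    Returns the alignment table plus counters
    ``{"mapped", "unmapped", "multimapped"}``.
    """
    counters = {"mapped": 0, "unmapped": 0, "multimapped": 0}
    if not reads:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS), counters

    by_len: dict[int, list[int]] = {}
    for i, (_, seq, _) in enumerate(reads):
        by_len.setdefault(len(seq), []).append(i)

    rows: list[tuple[str, str, int, str]] = []
    for L, idxs in sorted(by_len.items()):
        if L == 0:
            counters["unmapped"] += len(idxs)
            continue
        # sorted genome-wide window-hash index: (h1, h2) -> (chrom, pos)
        h1_parts, h2_parts, chrom_parts, pos_parts = [], [], [], []
        chrom_names = list(genome.keys())
        for ci, chrom in enumerate(chrom_names):
            codes = encode_sequence(genome[chrom])
            if len(codes) < L:
                continue
            valid = _window_valid(codes, L)
            h1 = _rolling_hashes(codes, L, _HASH_MULTIPLIERS[0])[valid]
            h2 = _rolling_hashes(codes, L, _HASH_MULTIPLIERS[1])[valid]
            h1_parts.append(h1)
            h2_parts.append(h2)
            chrom_parts.append(np.full(len(h1), ci, dtype=np.int32))
            pos_parts.append(np.flatnonzero(valid).astype(np.int64))
        if not h1_parts:
            counters["unmapped"] += len(idxs)
            continue
        g1 = np.concatenate(h1_parts)
        g2 = np.concatenate(h2_parts)
        gchrom = np.concatenate(chrom_parts)
        gpos = np.concatenate(pos_parts)
        order = np.lexsort((g2, g1))
        g1, g2, gchrom, gpos = g1[order], g2[order], gchrom[order], gpos[order]

        def batch_hashes(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            codes = np.stack([encode_sequence(s) for s in seqs])
            invalid = (codes == 4).any(axis=1)
            h = []
            for a in _HASH_MULTIPLIERS:
                pw = np.empty(L, dtype=np.uint64)
                pw[-1] = 1
                if L > 1:
                    np.multiply.accumulate(
                        np.full(L - 1, a, dtype=np.uint64), out=pw[-2::-1]
                    )
                h.append(
                    ((codes.astype(np.uint64) + np.uint64(1)) * pw[None, :]).sum(
                        axis=1, dtype=np.uint64
                    )
                )
            return h[0], h[1], invalid

        def match_counts(h1: np.ndarray, h2: np.ndarray):
            """Number of genome hits per query plus the index of the first."""
            lo = np.searchsorted(g1, h1, side="left")
            hi = np.searchsorted(g1, h1, side="right")
            n = np.zeros(len(h1), dtype=np.int64)
            first = np.full(len(h1), -1, dtype=np.int64)
            single = hi - lo == 1
            ok = np.zeros(len(h1), dtype=bool)
            ok[single] = g2[lo[single]] == h2[single]
            n[single & ok] = 1
            first[single & ok] = lo[single & ok]
            for q in np.flatnonzero(hi - lo > 1):  # rare shared-hash runs
                hits = np.flatnonzero(g2[lo[q] : hi[q]] == h2[q])
                n[q] = len(hits)
                if len(hits):
                    first[q] = lo[q] + hits[0]
            return n, first

        seqs = [reads[i][1] for i in idxs]
        f1, f2, bad_f = batch_hashes(seqs)
        r1, r2, _ = batch_hashes([revcomp(s) for s in seqs])
        nf, jf = match_counts(f1, f2)
        nr, jr = match_counts(r1, r2)
        nf[bad_f] = nr[bad_f] = 0  # non-ACGT reads never match
        total = nf + nr
        for q, i in enumerate(idxs):
            if bad_f[q] or total[q] == 0:
                counters["unmapped"] += 1
            elif total[q] > 1:
                counters["multimapped"] += 1
            else:
                j, strand = (jf[q], "+") if nf[q] else (jr[q], "-")
                rows.append(
                    (reads[i][0], chrom_names[int(gchrom[j])], int(gpos[j]), strand)
                )
                counters["mapped"] += 1
    aln = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return aln, counters


def dedup_alignments(alignments: pd.DataFrame) -> pd.DataFrame:
    """Keep one alignment per (chrom, start, strand) key.

    Among duplicates the first by read-name order survives (Picard-style
    single-end convention). Output is sorted by coordinate; the operation
    is idempotent.
    """
    if alignments.empty:
        return alignments.copy()
    df = alignments.sort_values(["chrom", "start", "strand", "qname"], kind="mergesort")
    df = df.drop_duplicates(subset=["chrom", "start", "strand"], keep="first")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def coverage_stats(
    alignments: pd.DataFrame, genome_length: int, read_length: int
) -> CoverageStats:
    """Breadth, genome-relative depth and covered-base depth.

    ``depth_genome`` = alignments x read_length / genome_length; breadth is
    the union of aligned intervals over the genome; ``depth_covered`` their
    ratio. Zero alignments give all-zero stats with a warning.
    """
    if len(alignments) == 0:
        warnings.warn("no alignments; coverage undefined, reporting zeros")
        return CoverageStats(breadth=0.0, depth_genome=0.0, depth_covered=0.0)
    depth_genome = len(alignments) * read_length / genome_length
    covered = 0
    for _, sub in alignments.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy())
        ends = starts + read_length
        # union of sorted equal-length intervals
        gap_new = np.ones(len(starts), dtype=bool)
        gap_new[1:] = starts[1:] >= ends[:-1]
        run_id = np.cumsum(gap_new) - 1
        run_start = np.minimum.reduceat(starts, np.flatnonzero(gap_new))
        run_end = np.maximum.reduceat(ends, np.flatnonzero(gap_new))
        covered += int((run_end - run_start).sum())
        del run_id
    breadth = covered / genome_length
    return CoverageStats(
        breadth=breadth,
        depth_genome=depth_genome,
        depth_covered=depth_genome / breadth,
    )
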