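"""Uniquely mappable positions and variable-width genomic bins.

A position is *uniquely mappable* for read length k when the k-mer starting
there occurs exactly once in the genome counting both strands (a k-mer equal
to the reverse complement of a k-mer elsewhere counts as a second
occurrence). The genome is then tiled into contiguous, non-overlapping
*variable bins* each holding a fixed number B of unique positions, so every
bin carries the same expected read count under uniform sampling while its
physical width varies with local mappability.

K-mer multiplicities are counted with a pair of independent 64-bit
polynomial rolling hashes over the 2-bit base encoding (collision
probability ~2^-128 per pair, vanishing at any realistic genome size); the
test suite checks the mask against a brute-force substring dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._io import encode_sequence

_HASH_MULTIPLIERS = (np.uint64(0x9E3779B97F4A7C15), np.uint64(0xC2B2AE3D27D4EB4F))
_U64 = np.uint64


@dataclass
class MappabilityMask:
    """Boolean per-start-position mask per chromosome for one read length."""

    read_length: int
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def n_unique(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.masks[chrom].sum())
        return int(sum(m.sum() for m in self.masks.values()))


def _rolling_hashes(codes: np.ndarray, k: int, a: np.uint64) -> np.ndarray:
    """Hash of every length-k window of ``codes`` (mod 2^64, wrapping)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=_U64)
    a_int = int(a)
    ainv = _U64(pow(a_int, -1, 1 << 64))
    idx = np.arange(n, dtype=_U64)
    apow = np.empty(n, dtype=_U64)
    ainvpow = np.empty(n, dtype=_U64)
    apow[0] = ainvpow[0] = 1
    if n > 1:
        np.multiply.accumulate(np.full(n - 1, a, dtype=_U64), out=apow[1:])
        np.multiply.accumulate(np.full(n - 1, ainv, dtype=_U64), out=ainvpow[1:])
    del idx
    terms = (codes.astype(_U64) + _U64(1)) * ainvpow
    prefix = np.zeros(n + 1, dtype=_U64)
    np.cumsum(terms, out=prefix[1:])
    # H(i) = sum_{t=i}^{i+k-1} (c_t+1) a^(i+k-1-t) = (P[i+k]-P[i]) * a^(i+k-1)
    return (prefix[k:] - prefix[: n - k + 1]) * apow[k - 1 :]


def _window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """True where the k-mer starting at a position contains only A/C/G/T."""
    bad = np.zeros(len(codes) + 1, dtype=np.int64)
    np.cumsum(codes == 4, out=bad[1:])
    return (bad[k:] - bad[: len(codes) - k + 1]) == 0


def compute_unique_positions(
    genome: Mapping[str, str], read_length: int
) -> MappabilityMask:
    """Mask of positions whose read-length k-mer is unique genome-wide.

    Both strands are counted; k-mers containing non-ACGT bases are
    non-unique by policy. Chromosomes shorter than the read length yield
    all-false masks.
    """
    k = read_length
    if k < 1:
        raise ValueError("read_length must be >= 1")
    chroms = list(genome.keys())
    fwd_hashes: dict[str, np.ndarray] = {}
    fwd_valid: dict[str, np.ndarray] = {}
    pools = []
    for chrom in chroms:
        codes = encode_sequence(genome[chrom])
        h = np.stack(
            [_rolling_hashes(codes, k, a) for a in _HASH_MULTIPLIERS], axis=1
        ) if len(codes) >= k else np.empty((0, 2), dtype=_U64)
        v = _window_valid(codes, k) if len(codes) >= k else np.empty(0, dtype=bool)
        fwd_hashes[chrom] = h
        fwd_valid[chrom] = v
        pools.append(h[v])
        # reverse-complement strand: hash windows of the reverse complement
        rc = (np.uint8(3) - codes[::-1]) % np.uint8(8)  # 4 ('other') maps to 7
        rc[codes[::-1] == 4] = 4
        if len(rc) >= k:
            hr = np.stack([_rolling_hashes(rc, k, a) for a in _HASH_MULTIPLIERS], axis=1)
            vr = _window_valid(rc, k)
            pools.append(hr[vr])
    if pools:
        pool = np.concatenate(pools, axis=0)
    else:
        pool = np.empty((0, 2), dtype=_U64)

    mask = MappabilityMask(read_length=k)
    if len(pool) == 0:
        for chrom in chroms:
            mask.masks[chrom] = np.zeros(len(genome[chrom]), dtype=bool)
        return mask

    order = np.lexsort((pool[:, 1], pool[:, 0]))
    spool = pool[order]
    new = np.ones(len(spool), dtype=bool)
    np.logical_or(
        spool[1:, 0] != spool[:-1, 0], spool[1:, 1] != spool[:-1, 1], out=new[1:]
    )
    uniq_keys = spool[new]
    counts = np.diff(np.append(np.flatnonzero(new), len(spool)))

    def lookup_counts(h: np.ndarray) -> np.ndarray:
        if len(h) == 0:
            return np.empty(0, dtype=np.int64)
        # locate each key among sorted unique keys (lexicographic on the pair)
        pos = np.searchsorted(uniq_keys[:, 0], h[:, 0], side="left")
        out = np.zeros(len(h), dtype=np.int64)
        # rows sharing the first hash word are rare; resolve exactly
        for i in range(len(h)):
            p = pos[i]
            while p < len(uniq_keys) and uniq_keys[p, 0] == h[i, 0]:
                if uniq_keys[p, 1] == h[i, 1]:
                    out[i] = counts[p]
                    break
                p += 1
        return out

    # vectorized exact pair lookup via a second lexsort-based merge
    def lookup_counts_fast(h: np.ndarray) -> np.ndarray:
        if len(h) == 0:
            return np.empty(0, dtype=np.int64)
        o = np.lexsort((h[:, 1], h[:, 0]))
        hs = h[o]
        res_sorted = np.zeros(len(h), dtype=np.int64)
        lo = np.searchsorted(uniq_keys[:, 0], hs[:, 0], side="left")
        hi = np.searchsorted(uniq_keys[:, 0], hs[:, 0], side="right")
        narrow = hi - lo == 1
        res_sorted[narrow] = np.where(
            uniq_keys[lo[narrow], 1] == hs[narrow, 1], counts[lo[narrow]], 0
        )
        wide = np.flatnonzero(~narrow)
        for i in wide:
            sl = slice(lo[i], hi[i])
            hit = np.flatnonzero(uniq_keys[sl, 1] == hs[i, 1])
            if len(hit):
                res_sorted[i] = counts[lo[i] + hit[0]]
        res = np.empty(len(h), dtype=np.int64)
        res[o] = res_sorted
        return res

    _ = lookup_counts  # slow reference path retained for clarity

    for chrom in chroms:
        m = np.zeros(len(genome[chrom]), dtype=bool)
        h, v = fwd_hashes[chrom], fwd_valid[chrom]
        if len(h):
            cnt = lookup_counts_fast(h)
            m[: len(h)] = v & (cnt == 1)
        mask.masks[chrom] = m
    return mask


# ---------------------------------------------------------------- binning

def build_variable_bins(
    mask: MappabilityMask, genome: Mapping[str, str], target_unique: int
) -> pd.DataFrame:
    """Tile each chromosome into contiguous bins of B unique positions.

    Scanning left to right, a bin closes immediately after accumulating
    ``target_unique`` unique positions; the next bin starts where the
    previous ended, so bins partition the covered extent with no gaps. The
    trailing partial bin is dropped. Returns a BED-like frame with columns
    ``chrom, start, end, unique_count, gc``.
    """
    if target_unique < 1:
        raise ValueError("target_unique must be >= 1")
    rows = []
    for chrom, m in mask.masks.items():
        idx = np.flatnonzero(m)
        n_bins = len(idx) // target_unique
        if n_bins == 0:
            warnings.warn(
                f"{chrom}: {len(idx)} unique positions < B={target_unique}; no bins"
            )
            continue
        codes = encode_sequence(genome[chrom])
        gc_prefix = np.zeros(len(codes) + 1, dtype=np.int64)
        np.cumsum((codes == 1) | (codes == 2), out=gc_prefix[1:])
        closers = idx[target_unique - 1 :: target_unique][:n_bins]
        starts = np.concatenate([[0], closers[:-1] + 1])
        ends = closers + 1
        gc = (gc_prefix[ends] - gc_prefix[starts]) / (ends - starts)
        for s, e, g in zip(starts, ends, gc):
            rows.append((chrom, int(s), int(e), target_unique, float(g)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "unique_count", "gc"])


def bin_size_summary(
    binset: pd.DataFrame, trim_top_fraction: float = 0.01
) -> tuple[float, float]:
    """Mean and sample SD of bin widths after trimming the widest bins.

    The largest ``floor(n * trim_top_fraction)`` bins by width are removed
    before computing statistics; SD uses the population convention (ddof=0).
    """
    if len(binset) == 0:
        raise ValueError("empty bin set")
    widths = np.sort((binset["end"] - binset["start"]).to_numpy())
    n_trim = int(np.floor(len(widths) * trim_top_fraction + 1e-9))
    kept = widths[: len(widths) - n_trim] if n_trim else widths
    if len(kept) == 0:
        raise ValueError("trim_top_fraction removed every bin")
    return float(kept.mean()), float(kept.std(ddof=0))
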